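"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/diffusion code paths: the
likelihood oracle enumerates every interior-node state assignment with
explicit transition probabilities, and the two-sex selection oracle iterates
the genotype-frequency recursion directly.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm


def enumerate_loglik(phy, tips, model, values):
    """Sum over all interior-state assignments: sum_k P(root) prod P_ij."""
    Q = model.build_q(values)
    k = len(model.states)
    edges = [(i, c, bl)
             for i in range(phy.n_nodes)
             for (c, bl) in phy.children[i]]
    P = {(i, c): expm(Q * bl) for (i, c, bl) in edges}
    internal = [i for i in range(phy.n_nodes) if phy.children[i]]
    tipmat = tips.reindex(phy.tip_labels).to_numpy()
    tip_row = dict(zip(phy.tip_ids, range(len(phy.tip_labels))))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = 1.0 / k  # equal root weighting
        for (i, c, _bl) in edges:
            si = amap[i]
            if c in amap:
                p *= P[(i, c)][si, amap[c]]
            else:
                p *= float(P[(i, c)][si] @ tipmat[tip_row[c]])
        total += p
    return math.log(total)


def iterate_sa_recursion(locus, n_generations=10_000, x0=0.5, y0=0.5):
    """Exact two-sex genotype-frequency recursion, iterated directly."""
    x, y = x0, y0
    for _ in range(n_generations):
        g_aa = x * y
        g_Aa = x * (1 - y) + (1 - x) * y
        g_AA = (1 - x) * (1 - y)
        wf = (g_AA * locus.w_f_AA, g_Aa * locus.w_f_Aa, g_aa * locus.w_f_aa)
        wm = (g_AA * locus.w_m_AA, g_Aa * locus.w_m_Aa, g_aa * locus.w_m_aa)
        x = (wf[2] + 0.5 * wf[1]) / sum(wf)
        y = (wm[2] + 0.5 * wm[1]) / sum(wm)
    return x, y


def hypergeom_two_sided_p(a, b, c, d):
    """Two-sided Fisher p by explicit enumeration of the hypergeometric
    support using exact rational-free arithmetic on log factorials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def log_comb(n_, k_):
        return (math.lgamma(n_ + 1) - math.lgamma(k_ + 1)
                - math.lgamma(n_ - k_ + 1))

    logs = np.array([log_comb(r1, x) + log_comb(r2, c1 - x) - log_comb(n, c1)
                     for x in range(lo, hi + 1)])
    obs = logs[a - lo]
    return float(np.exp(logs[logs <= obs + 1e-7]).sum())
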
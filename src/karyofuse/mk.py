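"""Constrained Mk models of karyotype evolution on phylogenies.

A continuous-time Markov chain on sex chromosome system states evolves along
a time-calibrated tree.  Two state spaces are supported:

* four states: male heterogametic unfused / fused, female heterogametic
  unfused / fused (``XY, XYF, ZW, ZWF``);
* six states distinguishing which chromosome fused: ``X1X2Y`` is a Y-A
  fusion, ``XY1Y2`` an X-A fusion, ``Z1Z2W`` a W-A fusion and ``ZW1W2`` a
  Z-A fusion.

The module provides Felsenstein-pruning likelihoods with per-branch matrix
exponentials, bounded maximum-likelihood fitting with named parameter
sharing (for likelihood-ratio model reduction), a slice-sampling MCMC with
independent exponential priors on all rates (the posterior of the fusion
rate difference ``q_XY.XYF - q_ZW.ZWF`` is the headline output), stochastic
character simulation, and approximate genus-level matching of a trait table
to tree tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = [
    "Phylogeny",
    "read_newick",
    "write_newick",
    "RateModel",
    "MatchReport",
    "match_taxa",
    "tip_state_matrix",
    "mk_likelihood",
    "MLFit",
    "fit_ml",
    "lrt",
    "McmcRun",
    "run_mcmc",
    "simulate_characters",
]

FOUR_STATES = ("XY", "XYF", "ZW", "ZWF")
SIX_STATES = ("XY", "X1X2Y", "XY1Y2", "ZW", "Z1Z2W", "ZW1W2")

#: fusion-class interpretation of the six-state space
SIX_STATE_FUSION = {"XY": None, "X1X2Y": "YA", "XY1Y2": "XA",
                    "ZW": None, "Z1Z2W": "WA", "ZW1W2": "ZA"}


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted tree with branch lengths, backed by a dendropy tree plus flat
    postorder arrays for fast likelihood evaluation."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    def _index(self) -> None:
        nodes = list(self._tree.postorder_node_iter())
        self._nodes = nodes
        self._node_id = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.tip_labels: List[str] = []
        self.tip_ids: List[int] = []
        self.children: List[List[Tuple[int, float]]] = [[] for _ in nodes]
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else ""
                self.tip_labels.append(label)
                self.tip_ids.append(i)
            else:
                for ch in nd.child_nodes():
                    bl = ch.edge.length if ch.edge.length is not None else 0.0
                    if bl < 0:
                        raise ValueError("negative branch length")
                    self.children[i].append((self._node_id[id(ch)], float(bl)))
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        self.root_id = self.n_nodes - 1

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def edge_lengths(self) -> List[float]:
        return [bl for ch in self.children for (_, bl) in ch]

    def retain_tips(self, labels: Iterable[str]) -> "Phylogeny":
        keep = set(labels)
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(list(keep))
        return Phylogeny(tree)

    def rename_tips(self, mapping: Dict[str, str]) -> "Phylogeny":
        tree = self._tree.clone(depth=1)
        for taxon in tree.taxon_namespace:
            if taxon.label in mapping:
                taxon.label = mapping[taxon.label]
        return Phylogeny(tree)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required or defaulting to 0)."""
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialise with enough digits to round-trip branch lengths to 1e-9."""
    return phy.dendropy_tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".12g").strip()


# ---------------------------------------------------------------------------
# Rate models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateModel:
    """A CTMC on karyotype states with named, shareable rate parameters.

    ``transitions`` maps state pairs to parameter names; several transitions
    may share one name (the sharing map used for likelihood-ratio model
    reduction).  ``root`` selects the root-state treatment: ``"equal"``
    (default, 1/k weights), ``"stationary"``, or ``"fitzjohn"``.
    """

    states: Tuple[str, ...]
    transitions: Tuple[Tuple[str, str, str], ...]
    root: str = "equal"

    def __post_init__(self) -> None:
        if self.root not in ("equal", "stationary", "fitzjohn"):
            raise ValueError("root must be equal, stationary, or fitzjohn")
        idx = {s: i for i, s in enumerate(self.states)}
        for a, b, _ in self.transitions:
            if a not in idx or b not in idx or a == b:
                raise ValueError(f"invalid transition {a}->{b}")

    @property
    def param_names(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for _, _, p in self.transitions:
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def build_q(self, values) -> np.ndarray:
        """Assemble the rate matrix from a parameter vector or name->value
        mapping; off-diagonals must be >= 0 and rows sum to zero."""
        if isinstance(values, dict):
            vals = values
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != (self.n_params,):
                raise ValueError("parameter vector has wrong length")
            vals = dict(zip(self.param_names, values))
        k = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((k, k))
        for a, b, p in self.transitions:
            v = float(vals[p])
            if v < 0:
                raise ValueError(f"rate {p} must be non-negative")
            Q[idx[a], idx[b]] += v
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    def share(self, mapping: Dict[str, str]) -> "RateModel":
        """Return a reduced model with parameters renamed per ``mapping``
        (e.g. ``{"q_XYF.XY": "q_fiss", "q_ZWF.ZW": "q_fiss"}``)."""
        new = tuple((a, b, mapping.get(p, p)) for a, b, p in self.transitions)
        return replace(self, transitions=new)

    # -- standard model constructors ------------------------------------

    @classmethod
    def four_state(cls, fused_turnover: bool = False, root: str = "equal") -> "RateModel":
        """Fusion/fission within each heterogamety system plus heterogamety
        turnover between unfused states (optionally also between fused)."""
        tr = [
            ("XY", "XYF", "q_XY.XYF"), ("XYF", "XY", "q_XYF.XY"),
            ("ZW", "ZWF", "q_ZW.ZWF"), ("ZWF", "ZW", "q_ZWF.ZW"),
            ("XY", "ZW", "q_XY.ZW"), ("ZW", "XY", "q_ZW.XY"),
        ]
        if fused_turnover:
            tr += [("XYF", "ZWF", "q_XYF.ZWF"), ("ZWF", "XYF", "q_ZWF.XYF")]
        return cls(states=FOUR_STATES, transitions=tuple(tr), root=root)

    @classmethod
    def six_state(cls, fused_turnover: bool = False, root: str = "equal") -> "RateModel":
        tr = [
            ("XY", "X1X2Y", "q_XY.X1X2Y"), ("X1X2Y", "XY", "q_X1X2Y.XY"),
            ("XY", "XY1Y2", "q_XY.XY1Y2"), ("XY1Y2", "XY", "q_XY1Y2.XY"),
            ("ZW", "Z1Z2W", "q_ZW.Z1Z2W"), ("Z1Z2W", "ZW", "q_Z1Z2W.ZW"),
            ("ZW", "ZW1W2", "q_ZW.ZW1W2"), ("ZW1W2", "ZW", "q_ZW1W2.ZW"),
            ("XY", "ZW", "q_XY.ZW"), ("ZW", "XY", "q_ZW.XY"),
        ]
        if fused_turnover:
            raise NotImplementedError("fused-state turnover is only defined "
                                      "for the four-state space")
        return cls(states=SIX_STATES, transitions=tuple(tr), root=root)

    def stationary_distribution(self, values) -> np.ndarray:
        Q = self.build_q(values)
        k = Q.shape[0]
        A = np.vstack([Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


# ---------------------------------------------------------------------------
# Taxon matching
# ---------------------------------------------------------------------------


@dataclass
class MatchReport:
    """Record of an approximate genus-matching run."""

    exact: List[str] = field(default_factory=list)
    substitutions: List[Tuple[str, str]] = field(default_factory=list)  # (tree tip, table species)
    pruned: List[str] = field(default_factory=list)
    unused_table_species: List[str] = field(default_factory=list)


def _genus(label: str, sep: str = "_") -> str:
    return label.split(sep)[0]


def match_taxa(tree: Phylogeny, table: pd.DataFrame, seed: int = 0,
               genus_sep: str = "_",
               max_per_genus: int = 2) -> Tuple[Phylogeny, pd.DataFrame, MatchReport]:
    """Align a species trait table with tree tips.

    1) species present in both tree and table are retained; 2) an unmatched
    tree tip may be replaced by a randomly chosen unmatched table species of
    the same genus, provided the genus would not exceed ``max_per_genus``
    representatives; 3) remaining unmatched tips are pruned.  Genus is the
    label prefix before ``genus_sep`` unless the table has a ``genus``
    column.  Returns the pruned/relabelled tree, the aligned table (rows in
    no particular order, indexed by species), and a :class:`MatchReport`.
    """
    if "species" not in table.columns:
        raise ValueError("table must have a 'species' column")
    rng = np.random.default_rng(seed)
    table = table.copy()
    if "genus" not in table.columns:
        table["genus"] = table["species"].map(lambda s: _genus(s, genus_sep))
    table_species = list(table["species"])
    table_set = set(table_species)
    tip_set = set(tree.tip_labels)
    if not table_set & tip_set:
        # genus substitution may still apply, but an empty exact intersection
        # with no shared genera is an outright mismatch
        tree_genera = {_genus(t, genus_sep) for t in tree.tip_labels}
        if not tree_genera & set(table["genus"]):
            raise ValueError("tree and species table share no species or genera")

    report = MatchReport()
    report.exact = sorted(table_set & tip_set)

    genus_reps: Dict[str, int] = {}
    for sp in report.exact:
        g = _genus(sp, genus_sep)
        genus_reps[g] = genus_reps.get(g, 0) + 1

    unmatched_tips = [t for t in tree.tip_labels if t not in table_set]
    unmatched_by_genus: Dict[str, List[str]] = {}
    matched_table = set(report.exact)
    for sp, g in zip(table["species"], table["genus"]):
        if sp not in matched_table:
            unmatched_by_genus.setdefault(g, []).append(sp)
    for g in unmatched_by_genus:
        unmatched_by_genus[g] = list(rng.permutation(unmatched_by_genus[g]))

    rename: Dict[str, str] = {}
    for tip in unmatched_tips:
        g = _genus(tip, genus_sep)
        candidates = unmatched_by_genus.get(g, [])
        if candidates and genus_reps.get(g, 0) < max_per_genus:
            sub = candidates.pop(0)
            rename[tip] = sub
            genus_reps[g] = genus_reps.get(g, 0) + 1
            report.substitutions.append((tip, sub))
        else:
            report.pruned.append(tip)

    kept_labels = report.exact + [t for t, _ in report.substitutions]
    if not kept_labels:
        raise ValueError("no tips could be matched to the species table")
    pruned = tree.retain_tips(kept_labels)
    if rename:
        pruned = pruned.rename_tips(rename)

    final_species = set(pruned.tip_labels)
    aligned = table[table["species"].isin(final_species)].set_index("species", drop=False)
    report.unused_table_species = sorted(table_set - final_species)
    return pruned, aligned, report


# ---------------------------------------------------------------------------
# Tip state matrices
# ---------------------------------------------------------------------------


def tip_state_matrix(table: pd.DataFrame, tip_labels: Sequence[str],
                     states: Sequence[str] = FOUR_STATES) -> pd.DataFrame:
    """Per-tip probability rows over states (1-hot for known states, uniform
    for tips that are missing from the table or flagged ambiguous).

    The table needs ``species`` and either a ``state`` column (literal state
    names) or ``heterogamety`` in {XY, ZW} plus ``fusion`` in
    {none, XA, YA, ZA, WA}.
    """
    states = tuple(states)
    k = len(states)
    rows = np.full((len(tip_labels), k), 1.0 / k)
    by_species = table.set_index("species") if "species" in table.columns else table
    for i, tip in enumerate(tip_labels):
        if tip not in by_species.index:
            continue
        rec = by_species.loc[tip]
        if isinstance(rec, pd.DataFrame):
            rec = rec.iloc[0]
        state = _state_of(rec, states)
        if state is None:
            continue
        rows[i] = 0.0
        rows[i, states.index(state)] = 1.0
    return pd.DataFrame(rows, index=list(tip_labels), columns=list(states))


def _state_of(rec: pd.Series, states: Tuple[str, ...]) -> Optional[str]:
    if "state" in rec.index and isinstance(rec["state"], str) and rec["state"]:
        return rec["state"] if rec["state"] in states else None
    het = rec.get("heterogamety")
    fus = rec.get("fusion", "none")
    if het not in ("XY", "ZW"):
        return None
    if not isinstance(fus, str) or fus in ("", "unknown"):
        return None
    if len(states) == 4:
        if fus == "none":
            return het
        if fus in ("XA", "YA") and het == "XY":
            return "XYF"
        if fus in ("ZA", "WA") and het == "ZW":
            return "ZWF"
        return None
    mapping = {("XY", "none"): "XY", ("XY", "YA"): "X1X2Y", ("XY", "XA"): "XY1Y2",
               ("ZW", "none"): "ZW", ("ZW", "WA"): "Z1Z2W", ("ZW", "ZA"): "ZW1W2"}
    return mapping.get((het, fus))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """e^{Q t} for every branch length, via eigendecomposition with a
    conditioning check and a scaling-and-squaring (scipy expm) fallback."""
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError
        E = np.exp(np.multiply.outer(lengths, w))  # (n, k)
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
        P = np.real_if_close(P, tol=1e6).real
    except np.linalg.LinAlgError:
        P = np.stack([sla.expm(Q * t) for t in lengths])
    P = np.clip(P, 0.0, None)
    rowsums = P.sum(axis=2, keepdims=True)
    if not np.allclose(rowsums, 1.0, atol=1e-8):
        raise ArithmeticError("non-finite or non-stochastic transition matrix")
    return P / rowsums


def _root_weights(model: RateModel, values, partial: np.ndarray) -> np.ndarray:
    k = len(model.states)
    if model.root == "equal":
        return np.full(k, 1.0 / k)
    if model.root == "stationary":
        return model.stationary_distribution(values)
    # FitzJohn: weight each root state by its share of the data likelihood
    tot = partial.sum()
    return partial / tot if tot > 0 else np.full(k, 1.0 / k)


class _PruningEngine:
    """Precomputed pruning schedule for repeated likelihood evaluation.

    Internal nodes are grouped into levels (all children already resolved),
    so each level is one batched branch-transform plus a segmented product;
    this keeps per-evaluation Python overhead proportional to tree depth
    rather than tree size.
    """

    def __init__(self, tree: Phylogeny, tips: pd.DataFrame, model: RateModel):
        states = list(model.states)
        if list(tips.columns) != states:
            raise ValueError("tip matrix columns must match model states")
        tip_rows = tips.reindex(tree.tip_labels)
        if tip_rows.isna().any().any():
            missing = set(tree.tip_labels) - set(tips.index)
            raise ValueError(f"tip matrix missing rows for {sorted(missing)[:5]}")
        self.model = model
        self.k = len(states)
        self.n_nodes = tree.n_nodes
        self.root_id = tree.root_id
        self.tip_partials = np.zeros((tree.n_nodes, self.k))
        for tid, label in zip(tree.tip_ids, tree.tip_labels):
            self.tip_partials[tid] = tip_rows.loc[label].to_numpy()

        level = np.zeros(tree.n_nodes, dtype=int)
        for i in range(tree.n_nodes):
            if tree.children[i]:
                level[i] = 1 + max(level[c] for c, _ in tree.children[i])
        # edges sorted by (parent level, parent id): segments contiguous
        edges = [(level[i], i, c, bl)
                 for i in range(tree.n_nodes) if tree.children[i]
                 for c, bl in tree.children[i]]
        edges.sort(key=lambda t: (t[0], t[1]))
        self.edge_child = np.array([c for _, _, c, _ in edges], dtype=int)
        self.edge_len = np.array([bl for _, _, _, bl in edges])
        self.levels: List[Tuple[slice, np.ndarray, np.ndarray]] = []
        pos = 0
        max_level = int(level.max())
        for lv in range(1, max_level + 1):
            seg = [j for j, (elv, *_rest) in enumerate(edges) if elv == lv]
            if not seg:
                continue
            sl = slice(seg[0], seg[-1] + 1)
            parents_all = [edges[j][1] for j in seg]
            starts, parents = [], []
            for j, p in enumerate(parents_all):
                if not parents or parents[-1] != p:
                    starts.append(j)
                    parents.append(p)
            self.levels.append((sl, np.array(starts, dtype=int),
                                np.array(parents, dtype=int)))
            pos = sl.stop
        assert pos == len(edges)

    def loglik(self, values) -> float:
        Q = self.model.build_q(values)
        P = _transition_matrices(Q, self.edge_len)
        partials = self.tip_partials.copy()
        log_scale = 0.0
        for sl, starts, parents in self.levels:
            T = np.einsum("eij,ej->ei", P[sl], partials[self.edge_child[sl]])
            prods = np.multiply.reduceat(T, starts, axis=0)
            m = prods.max(axis=1)
            if np.any(m <= 0):
                return -math.inf
            partials[parents] = prods / m[:, None]
            log_scale += float(np.log(m).sum())
        root_partial = partials[self.root_id]
        weights = _root_weights(self.model, values, root_partial)
        lik = float(weights @ root_partial)
        if lik <= 0:
            return -math.inf
        return math.log(lik) + log_scale


def mk_likelihood(tree: Phylogeny, tips: pd.DataFrame, model: RateModel,
                  values) -> float:
    """Felsenstein-pruning log-likelihood of tip states under the model.

    ``tips`` is a tip-by-state probability matrix (see
    :func:`tip_state_matrix`); rows are matched to tree tips by index label.
    """
    return _PruningEngine(tree, tips, model).loglik(values)


# ---------------------------------------------------------------------------
# Maximum likelihood and model comparison
# ---------------------------------------------------------------------------


@dataclass
class MLFit:
    model: RateModel
    params: Dict[str, float]
    loglik: float
    converged: bool
    n_starts: int

    @property
    def n_free(self) -> int:
        return self.model.n_params


_LOG_LO, _LOG_HI = math.log(1e-8), math.log(1e3)


def fit_ml(tree: Phylogeny, tips: pd.DataFrame, model: RateModel,
           n_starts: int = 3, seed: int = 0,
           start_values: Optional[Sequence[float]] = None) -> MLFit:
    """Bounded multi-start ML estimation of the free rates (log scale,
    L-BFGS-B).  Deterministic given ``seed``; non-convergence of every start
    is flagged on the returned fit rather than raised."""
    rng = np.random.default_rng(seed)
    npar = model.n_params
    engine = _PruningEngine(tree, tips, model)

    def negloglik(log_theta: np.ndarray) -> float:
        ll = engine.loglik(np.exp(log_theta))
        return 1e10 if not np.isfinite(ll) else -ll

    starts = [np.full(npar, math.log(0.05))]
    if start_values is not None:
        starts.insert(0, np.log(np.clip(start_values, 1e-8, None)))
    while len(starts) < n_starts:
        starts.append(np.log(0.05) + rng.normal(0.0, 1.5, size=npar))

    best = None
    any_ok = False
    for x0 in starts[:n_starts]:
        res = minimize(negloglik, x0, method="L-BFGS-B",
                       bounds=[(_LOG_LO, _LOG_HI)] * npar,
                       options={"maxiter": 500, "ftol": 1e-12})
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = dict(zip(model.param_names, np.exp(best.x)))
    return MLFit(model=model, params=params, loglik=-best.fun,
                 converged=any_ok, n_starts=n_starts)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    refitted: bool = False


def lrt(full: MLFit, reduced: MLFit, tree: Optional[Phylogeny] = None,
        tips: Optional[pd.DataFrame] = None) -> LRTResult:
    """Likelihood-ratio test of a reduced (parameter-sharing) model against
    the full model: 2 dlogL ~ chi^2 with df = difference in free rates.

    A materially negative statistic indicates a poorly converged full fit;
    when the data are supplied the full model is refitted from the reduced
    optimum before testing.
    """
    df = full.n_free - reduced.n_free
    if df <= 0:
        raise ValueError("reduced model must have fewer free parameters")
    stat = 2.0 * (full.loglik - reduced.loglik)
    refitted = False
    if stat < -1e-6 and tree is not None and tips is not None:
        shared = [reduced.params[_shared_name(full.model, reduced.model, p)]
                  for p in full.model.param_names]
        full = fit_ml(tree, tips, full.model, n_starts=1, start_values=shared)
        stat = 2.0 * (full.loglik - reduced.loglik)
        refitted = True
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)),
                     refitted=refitted)


def _shared_name(full_model: RateModel, reduced_model: RateModel, param: str) -> str:
    for (a, b, p), (_, _, q) in zip(full_model.transitions, reduced_model.transitions):
        if p == param:
            return q
    raise KeyError(param)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass
class McmcRun:
    """Posterior sample of the rate parameters.

    ``samples`` has one row per recorded sweep with the rates, the
    log-posterior, and any derived difference series.  ``burn_in`` rows are
    dropped by the summary accessors.
    """

    samples: pd.DataFrame
    prior_mean: float
    n_steps: int
    burn_in: int
    seed: int
    derived: Tuple[str, str]

    @property
    def posterior(self) -> pd.DataFrame:
        return self.samples.iloc[self.burn_in:]

    @property
    def difference(self) -> pd.Series:
        a, b = self.derived
        return self.posterior[a] - self.posterior[b]

    def fraction_positive(self) -> float:
        d = self.difference
        return float((d > 0).mean())

    def credibility_interval(self, level: float = 0.95) -> Tuple[float, float]:
        d = self.difference
        lo = (1.0 - level) / 2.0
        return (float(d.quantile(lo)), float(d.quantile(1.0 - lo)))

    def effective_sample_size(self, column: Optional[str] = None) -> float:
        x = (self.difference if column is None else self.posterior[column]).to_numpy()
        n = len(x)
        if n < 10 or np.var(x) == 0:
            return float(n)
        xc = x - x.mean()
        acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
        s = 1.0
        for t in range(1, min(n // 2, 1000)):
            if acf[t] < 0.05:
                break
            s += 2.0 * acf[t]
        return float(n / s)


def _slice_sample(logpost, x0: float, ll0: float, rng: np.random.Generator,
                  w: float = 0.1, max_steps: int = 50) -> Tuple[float, float]:
    """Univariate slice sampler on [0, inf) with stepping-out and shrinkage."""
    log_y = ll0 + math.log(rng.random())
    u = rng.random() * w
    lo = max(x0 - u, 0.0)
    hi = x0 + (w - u)
    for _ in range(max_steps):
        if lo <= 0.0 or logpost(lo) < log_y:
            break
        lo = max(lo - w, 0.0)
    for _ in range(max_steps):
        if logpost(hi) < log_y:
            break
        hi += w
    while True:
        x1 = lo + rng.random() * (hi - lo)
        ll1 = logpost(x1)
        if ll1 >= log_y:
            return x1, ll1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def run_mcmc(tree: Optional[Phylogeny], tips: Optional[pd.DataFrame],
             model: RateModel, prior_mean: float = 0.05,
             n_steps: int = 50_000, burn_in: int = 10_000, seed: int = 0,
             derived: Optional[Tuple[str, str]] = None,
             slice_width: Optional[float] = None) -> McmcRun:
    """Slice-sampling MCMC over the model's free rates.

    The posterior is likelihood x independent Exp(mean ``prior_mean``) priors
    on every rate.  One sweep updates each parameter in turn by univariate
    slice sampling; every sweep is recorded.  Passing ``tree=None`` (or
    ``tips=None``) runs a prior-only chain (flat likelihood), used for prior
    recovery diagnostics.  The derived difference series defaults to the
    fusion-rate contrast ``q_XY.XYF - q_ZW.ZWF`` when those parameters exist.
    """
    if burn_in >= n_steps:
        raise ValueError("burn_in must be smaller than n_steps")
    names = list(model.param_names)
    if derived is None:
        if "q_XY.XYF" in names and "q_ZW.ZWF" in names:
            derived = ("q_XY.XYF", "q_ZW.ZWF")
        else:
            derived = (names[0], names[1] if len(names) > 1 else names[0])
    rng = np.random.default_rng(seed)
    rate = 1.0 / prior_mean
    w = slice_width if slice_width is not None else 2.0 * prior_mean
    prior_only = tree is None or tips is None
    engine = None if prior_only else _PruningEngine(tree, tips, model)

    theta = np.full(len(names), prior_mean)

    def logpost(vec: np.ndarray) -> float:
        lp = -rate * float(vec.sum())
        if prior_only:
            return lp
        ll = engine.loglik(vec)
        return lp + ll if np.isfinite(ll) else -math.inf

    current = logpost(theta)
    rows = np.empty((n_steps, len(names) + 1))
    for step in range(n_steps):
        for j in range(len(names)):
            def cond(v, j=j):
                t = theta.copy()
                t[j] = v
                return logpost(t)
            theta[j], current = _slice_sample(cond, theta[j], current, rng, w=w)
        rows[step, :-1] = theta
        rows[step, -1] = current
    samples = pd.DataFrame(rows, columns=names + ["log_posterior"])
    return McmcRun(samples=samples, prior_mean=prior_mean, n_steps=n_steps,
                   burn_in=burn_in, seed=seed, derived=derived)


# ---------------------------------------------------------------------------
# Character simulation
# ---------------------------------------------------------------------------


def simulate_characters(tree: Phylogeny, model: RateModel, values,
                        root_state: Optional[str] = None,
                        seed: int = 0) -> Tuple[pd.DataFrame, Dict[int, str]]:
    """Stochastic (Gillespie) simulation of the CTMC along every branch.

    Returns a 1-hot tip state matrix and the full node-state map (node ids in
    the tree's postorder indexing).  ``root_state=None`` draws the root from
    the chain's stationary distribution — the natural generative default for
    a clade old enough to be at equilibrium (the likelihood-side root
    weighting is a separate setting on the model).
    """
    rng = np.random.default_rng(seed)
    Q = model.build_q(values)
    states = list(model.states)
    k = len(states)
    if root_state is None:
        weights = model.stationary_distribution(values)
        if not np.all(np.isfinite(weights)) or weights.sum() <= 0:
            weights = np.full(k, 1.0 / k)
        root_idx = int(rng.choice(k, p=weights))
    else:
        root_idx = states.index(root_state)

    node_state: Dict[int, int] = {tree.root_id: root_idx}
    # walk edges in preorder (reverse postorder)
    for i in range(tree.n_nodes - 1, -1, -1):
        for (child, bl) in tree.children[i]:
            s = node_state[i]
            t = 0.0
            while True:
                out = -Q[s, s]
                if out <= 0:
                    break
                t += rng.exponential(1.0 / out)
                if t >= bl:
                    break
                probs = np.clip(Q[s], 0.0, None)
                probs[s] = 0.0
                probs /= probs.sum()
                s = int(rng.choice(k, p=probs))
            node_state[child] = s

    rows = np.zeros((tree.n_tips, k))
    for r, (tid, label) in enumerate(zip(tree.tip_ids, tree.tip_labels)):
        rows[r, node_state[tid]] = 1.0
    tips = pd.DataFrame(rows, index=list(tree.tip_labels), columns=states)
    node_states = {i: states[s] for i, s in node_state.items()}
    return tips, node_states
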
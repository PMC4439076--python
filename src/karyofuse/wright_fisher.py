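"""Forward-in-time Wright-Fisher simulation of a fusion mutation's fate.

The simulator realises the generative model behind the diffusion results in
:mod:`karyofuse.popgen`: discrete non-overlapping generations, ``N_f``
reproductively successful mothers and ``N_m`` fathers sampled each generation
by multinomial gamete sampling, viability selection on offspring genotypes,
meiotic drive applied at gametogenesis in fusion heterozygotes of the driving
sex, and (optionally) a sexually antagonistic locus in complete linkage with
the fused sex-determining region.

Replicates are tracked as genotype-category counts and advanced in vectorised
batches, so several hundred thousand replicates are feasible on one CPU.
Runs that are still segregating when the generation cap is reached are
reported separately, never silently counted as losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .popgen import (
    ChromosomeClass,
    DirectSelection,
    DriveScheme,
    PopulationConfig,
    SALocus,
    sa_equilibrium,
)

__all__ = ["SimConfig", "FixationSummary", "simulate_fusion_fate", "simulate_sa_capture"]

# class copies carried per female / per male
_COPIES = {"X": (2, 1), "Y": (0, 1), "Z": (1, 2), "W": (1, 0)}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation experiment.

    ``scenario`` is a :class:`DirectSelection`, a :class:`DriveScheme`, or an
    :class:`SALocus` (handled by :func:`simulate_sa_capture`).  ``initial_copies``
    supports 1 (a single new fusion) or ``n_c - 1`` (a single unfused copy,
    used for drive mirror-symmetry checks).  ``max_generations`` defaults to
    100 x the class copy number.
    """

    population: PopulationConfig
    chromosome: ChromosomeClass
    scenario: Union[DirectSelection, DriveScheme, SALocus, None] = None
    replicates: int = 10_000
    max_generations: Optional[int] = None
    seed: int = 0
    initial_copies: int = 1
    captured_allele: Optional[str] = None  # SA runs: 'a', 'A', or None = by frequency

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.max_generations is not None and self.max_generations < 1:
            raise ValueError("max_generations must be at least 1")

    @property
    def n_copies(self) -> int:
        return ChromosomeClass(self.chromosome).copy_count(self.population)

    @property
    def generation_cap(self) -> int:
        return self.max_generations if self.max_generations is not None else 100 * self.n_copies


@dataclass(frozen=True)
class FixationSummary:
    """Outcome counts of a batch of replicate trajectories."""

    n_fixed: int
    n_lost: int
    n_segregating_at_cap: int
    fixation_prob_estimate: float
    standard_error: float
    mean_fixation_time: float
    replicates: int
    config: Optional[SimConfig] = field(default=None, repr=False, compare=False)

    @classmethod
    def from_counts(cls, n_fixed: int, n_lost: int, n_capped: int,
                    fix_times: np.ndarray, config: Optional[SimConfig] = None) -> "FixationSummary":
        n = n_fixed + n_lost + n_capped
        p = n_fixed / n
        se = math.sqrt(p * (1.0 - p) / n)
        tbar = float(np.mean(fix_times)) if len(fix_times) else math.nan
        return cls(n_fixed=n_fixed, n_lost=n_lost, n_segregating_at_cap=n_capped,
                   fixation_prob_estimate=p, standard_error=se,
                   mean_fixation_time=tbar, replicates=n, config=config)


# ---------------------------------------------------------------------------
# Single-locus engine: direct selection and meiotic drive
# ---------------------------------------------------------------------------


def _genotype_weights(selection: DirectSelection, sex: str) -> Tuple[float, float, float]:
    s = selection.coefficient(sex)
    h = selection.h
    return 1.0, 1.0 + 2.0 * h * s, 1.0 + 2.0 * s


def _sample_three(rng: np.random.Generator, n: int, q0: np.ndarray, q1: np.ndarray,
                  q2: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised multinomial over three categories via sequential binomials."""
    tot = q0 + q1 + q2
    p2 = np.clip(q2 / tot, 0.0, 1.0)
    n2 = rng.binomial(n, p2)
    rest = np.clip(q0 + q1, 1e-300, None)
    p1 = np.clip(q1 / rest, 0.0, 1.0)
    n1 = rng.binomial(n - n2, p1)
    n0 = n - n2 - n1
    return n0, n1, n2


def simulate_fusion_fate(config: SimConfig) -> FixationSummary:
    """Track a fusion mutation to fixation, loss, or the generation cap.

    The fusion starts as ``initial_copies`` copies placed in adults; a single
    copy is carried by a female or male with probability proportional to each
    sex's share of the class's copies (e.g. 2N_f/(2N_f + N_m) for X).
    """
    scenario = config.scenario
    if isinstance(scenario, SALocus):
        return simulate_sa_capture(config)
    selection = scenario if isinstance(scenario, DirectSelection) else DirectSelection()
    drive = scenario if isinstance(scenario, DriveScheme) else None

    pop = config.population
    chrom = ChromosomeClass(config.chromosome)
    k_f, k_m = _COPIES[chrom.value]
    N_f, N_m = pop.N_f, pop.N_m
    n_c = config.n_copies
    R = config.replicates
    cap = config.generation_cap
    rng = np.random.default_rng(config.seed)

    if config.initial_copies not in (1, n_c - 1):
        raise ValueError("initial_copies must be 1 or n_copies - 1")

    tau_f = (1.0 + drive.f) / 2.0 if (drive and drive.driving_sex == "female") else 0.5
    tau_m = (1.0 + drive.f) / 2.0 if (drive and drive.driving_sex == "male") else 0.5
    # fertility-like weight on class-bearing gametes of hemizygous fused carriers
    wt_f = 1.0 + drive.f if (drive and drive.driving_sex == "female") else 1.0
    wt_m = 1.0 + drive.f if (drive and drive.driving_sex == "male") else 1.0

    w_f = _genotype_weights(selection, "f")
    w_m = _genotype_weights(selection, "m")

    # State: female counts by fused-copy count (R, k_f+1); same for males.
    F = np.zeros((R, k_f + 1), dtype=np.int64) if k_f else None
    M = np.zeros((R, k_m + 1), dtype=np.int64) if k_m else None
    if F is not None:
        F[:, 0] = N_f
    if M is not None:
        M[:, 0] = N_m

    # Initial placement: single fused (or single unfused) copy.
    single_unfused = config.initial_copies == n_c - 1
    if single_unfused:
        if F is not None:
            F[:, 0] = 0
            F[:, k_f] = N_f
        if M is not None:
            M[:, 0] = 0
            M[:, k_m] = N_m
    p_female_carrier = chrom.copies_in_females(pop) / n_c
    in_female = rng.random(R) < p_female_carrier
    for sex_mask, state, k in ((in_female, F, k_f), (~in_female, M, k_m)):
        if state is None:
            continue
        idx = np.where(sex_mask)[0]
        if single_unfused:
            state[idx, k] -= 1
            state[idx, k - 1] += 1
        else:
            state[idx, 0] -= 1
            state[idx, 1] += 1

    active = np.arange(R)
    n_fixed = 0
    n_lost = 0
    fix_times: List[int] = []
    gen = 0

    while len(active) and gen < cap:
        gen += 1
        Fa = F[active] if F is not None else None
        Ma = M[active] if M is not None else None

        # Class-gamete fused frequency from each sex.
        if Fa is not None:
            if k_f == 2:
                p_f = (Fa[:, 2] + tau_f * Fa[:, 1]) / N_f
            else:  # k_f == 1
                p_f = Fa[:, 1] * wt_f / (Fa[:, 1] * wt_f + Fa[:, 0])
        if Ma is not None:
            if k_m == 2:
                p_m = (Ma[:, 2] + tau_m * Ma[:, 1]) / N_m
            else:
                p_m = Ma[:, 1] * wt_m / (Ma[:, 1] * wt_m + Ma[:, 0])

        # Next-generation mothers.
        if chrom is ChromosomeClass.X:
            q2 = p_f * p_m
            q1 = p_f * (1 - p_m) + (1 - p_f) * p_m
            q0 = (1 - p_f) * (1 - p_m)
            F_new = np.stack(_sample_three(rng, N_f, q0 * w_f[0], q1 * w_f[1], q2 * w_f[2]), axis=1)
        elif chrom is ChromosomeClass.Z:  # daughters get father's Z only
            q1 = p_m
            p = q1 * w_f[1] / (q1 * w_f[1] + (1 - q1) * w_f[0])
            n1 = rng.binomial(N_f, p)
            F_new = np.stack([N_f - n1, n1], axis=1)
        elif chrom is ChromosomeClass.W:  # daughters get mother's W only
            q1 = p_f
            p = q1 * w_f[1] / (q1 * w_f[1] + (1 - q1) * w_f[0])
            n1 = rng.binomial(N_f, p)
            F_new = np.stack([N_f - n1, n1], axis=1)
        else:  # Y: females carry no state
            F_new = None

        # Next-generation fathers.
        if chrom is ChromosomeClass.Z:
            q2 = p_f * p_m
            q1 = p_f * (1 - p_m) + (1 - p_f) * p_m
            q0 = (1 - p_f) * (1 - p_m)
            M_new = np.stack(_sample_three(rng, N_m, q0 * w_m[0], q1 * w_m[1], q2 * w_m[2]), axis=1)
        elif chrom is ChromosomeClass.X:  # sons get mother's X only
            q1 = p_f
            p = q1 * w_m[1] / (q1 * w_m[1] + (1 - q1) * w_m[0])
            n1 = rng.binomial(N_m, p)
            M_new = np.stack([N_m - n1, n1], axis=1)
        elif chrom is ChromosomeClass.Y:  # sons get father's Y
            q1 = p_m
            p = q1 * w_m[1] / (q1 * w_m[1] + (1 - q1) * w_m[0])
            n1 = rng.binomial(N_m, p)
            M_new = np.stack([N_m - n1, n1], axis=1)
        else:  # W: males carry no state
            M_new = None

        copies = np.zeros(len(active), dtype=np.int64)
        if F_new is not None:
            F[active] = F_new
            copies += F_new @ np.arange(k_f + 1)
        if M_new is not None:
            M[active] = M_new
            copies += M_new @ np.arange(k_m + 1)

        fixed = copies == n_c
        lost = copies == 0
        n_fixed += int(fixed.sum())
        n_lost += int(lost.sum())
        fix_times.extend([gen] * int(fixed.sum()))
        active = active[~(fixed | lost)]

    n_capped = len(active)
    return FixationSummary.from_counts(n_fixed, n_lost, n_capped,
                                       np.asarray(fix_times, dtype=float), config)


# ---------------------------------------------------------------------------
# Two-locus engine: fusion x sexually antagonistic allele
# ---------------------------------------------------------------------------
#
# Individual categories per sex: (c fused class copies, a-count among attached
# alleles, a-count among the 2 - c free autosome copies).  Gamete types:
# class-bearing (fused flag x allele) -> indices 0..3 as (U,A),(U,a),(F,A),(F,a);
# plain (autosome-only) gametes -> indices 0..1 as A, a.


def _sa_categories(k: int) -> List[Tuple[int, int, int]]:
    cats = []
    for c in range(k + 1):
        for att in range(c + 1):
            for free in range(2 - c + 1):
                cats.append((c, att, free))
    return cats


def _class_gamete_matrix(cats: List[Tuple[int, int, int]], k: int) -> np.ndarray:
    """Per-category distribution over class-gamete types (U/F x A/a) for a
    sex carrying ``k`` class copies.

    A fused copy travels with its attached allele; an unfused copy picks up a
    free allele.  For two-copy carriers the transmitted copy is chosen
    uniformly (SA runs carry no drive).
    """
    G = np.zeros((len(cats), 4))
    for i, (c, att, free) in enumerate(cats):
        if k == 1:
            if c == 1:
                G[i, 2 + att] = 1.0
            else:
                pa = free / 2.0
                G[i, 0], G[i, 1] = 1.0 - pa, pa
        else:
            if c == 2:
                pa = att / 2.0
                G[i, 2], G[i, 3] = 1.0 - pa, pa
            elif c == 1:
                G[i, 2], G[i, 3] = 0.5 * (1 - att), 0.5 * att
                G[i, 0], G[i, 1] = 0.5 * (1 - free), 0.5 * free
            else:
                pa = free / 2.0
                G[i, 0], G[i, 1] = 1.0 - pa, pa
    return G


def _plain_gamete_matrix(cats: List[Tuple[int, int, int]]) -> np.ndarray:
    """Per-category distribution over plain (autosome-only) gamete alleles.

    For a 1-copy carrier (c=1) the non-class gamete carries the free allele;
    for non-carriers it carries a random free allele.
    """
    G = np.zeros((len(cats), 2))
    for i, (c, att, free) in enumerate(cats):
        if c == 1:
            pa = float(free)
        else:  # c == 0 (k<=1 sexes only produce plain gametes at c<=1)
            pa = free / 2.0
        G[i, 0] = 1.0 - pa
        G[i, 1] = pa
    return G


def _combine_map(cats_out: List[Tuple[int, int, int]], t1_class: bool,
                 t2_class: bool) -> np.ndarray:
    """Tensor T[i, j, cat] mapping a pair of gamete types to the offspring
    category."""
    n1 = 4 if t1_class else 2
    n2 = 4 if t2_class else 2
    index = {cat: k for k, cat in enumerate(cats_out)}
    T = np.zeros((n1, n2, len(cats_out)))
    for i in range(n1):
        for j in range(n2):
            f1, a1 = (i // 2, i % 2) if t1_class else (None, i)
            f2, a2 = (j // 2, j % 2) if t2_class else (None, j)
            c = (f1 or 0) + (f2 or 0)
            att = (a1 if f1 else 0) + (a2 if f2 else 0)
            free = (a1 if (t1_class and not f1) or not t1_class else 0) + \
                   (a2 if (t2_class and not f2) or not t2_class else 0)
            T[i, j, index[(c, att, free)]] = 1.0
    return T


def _sa_fitness_vector(cats: List[Tuple[int, int, int]], locus: SALocus, sex: str) -> np.ndarray:
    fit = locus.female_fitness if sex == "f" else locus.male_fitness
    return np.array([fit(att + free) for (_, att, free) in cats])


def _sample_categories(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    """Vectorised multinomial: probs (R, C) -> integer counts (R, C)."""
    R, C = probs.shape
    counts = np.zeros((R, C), dtype=np.int64)
    remaining = np.full(R, n, dtype=np.int64)
    tail = probs[:, ::-1].cumsum(axis=1)[:, ::-1]
    for c in range(C - 1):
        denom = np.clip(tail[:, c], 1e-300, None)
        p = np.clip(probs[:, c] / denom, 0.0, 1.0)
        draw = rng.binomial(remaining, p)
        counts[:, c] = draw
        remaining -= draw
    counts[:, C - 1] = remaining
    return counts


def simulate_sa_capture(config: SimConfig) -> FixationSummary:
    """Fate of a fusion that captures an allele at a sexually antagonistic
    locus held polymorphic at its two-sex equilibrium.

    The resident population starts at the equilibrium genotype frequencies;
    the new fusion is completely linked to its captured allele (no
    recombination once fused; free recombination of the locus otherwise).
    """
    locus = config.scenario
    if not isinstance(locus, SALocus):
        raise TypeError("simulate_sa_capture requires an SALocus scenario")
    eq = sa_equilibrium(locus)
    if not eq.polymorphic:
        raise ValueError("SA locus admits no protected polymorphism")

    pop = config.population
    chrom = ChromosomeClass(config.chromosome)
    k_f, k_m = _COPIES[chrom.value]
    N_f, N_m = pop.N_f, pop.N_m
    n_c = config.n_copies
    R = config.replicates
    cap = config.generation_cap
    rng = np.random.default_rng(config.seed)
    if config.initial_copies != 1:
        raise ValueError("SA capture runs start from a single fused copy")

    cats_f = _sa_categories(k_f)
    cats_m = _sa_categories(k_m)
    Cf, Cm = len(cats_f), len(cats_m)
    Gc_f = _class_gamete_matrix(cats_f, k_f) if k_f else None
    Gc_m = _class_gamete_matrix(cats_m, k_m) if k_m else None
    Gp_f = _plain_gamete_matrix(cats_f)
    Gp_m = _plain_gamete_matrix(cats_m)
    wvec_f = _sa_fitness_vector(cats_f, locus, "f")
    wvec_m = _sa_fitness_vector(cats_m, locus, "m")
    fused_f = np.array([c for c, _, _ in cats_f])
    fused_m = np.array([c for c, _, _ in cats_m])

    # Offspring recipes: which gamete types daughters / sons receive.
    # (mother_class?, father_class?) per offspring sex.
    recipes = {
        "X": {"d": (True, True), "s": (True, False)},
        "Y": {"d": (False, False), "s": (False, True)},
        "Z": {"d": (False, True), "s": (True, True)},
        "W": {"d": (True, False), "s": (False, True)},
    }[chrom.value]
    # W sons: mother plain (her Z carries the free allele) x father plain?
    # Fathers in a W run carry no W: both their gametes are plain.
    if chrom is ChromosomeClass.W:
        recipes = {"d": (True, False), "s": (False, False)}

    T_d = _combine_map(cats_f, *recipes["d"])
    T_s = _combine_map(cats_m, *recipes["s"])

    x, y = eq.x_egg, eq.y_sperm

    def resident_probs(cats, wvec):
        """Adult (post-selection) resident category probabilities."""
        g = np.array([(1 - x) * (1 - y), x * (1 - y) + (1 - x) * y, x * y])
        probs = np.zeros(len(cats))
        for i, (c, att, free) in enumerate(cats):
            if c == 0:
                probs[i] = g[free] * wvec[i]
        return probs / probs.sum()

    res_f = resident_probs(cats_f, wvec_f)
    res_m = resident_probs(cats_m, wvec_m)

    F = _sample_categories(rng, N_f, np.tile(res_f, (R, 1)))
    M = _sample_categories(rng, N_m, np.tile(res_m, (R, 1)))

    # Introduce the fused copy: carrier sex ~ copy share; captured allele by
    # pool frequency of the sex of origin unless pinned; the carrier's free
    # allele comes from the opposite gamete pool.
    p_female_carrier = chrom.copies_in_females(pop) / n_c
    in_female = rng.random(R) < p_female_carrier
    if config.captured_allele is None:
        cap_a_f = rng.random(R) < x  # female-origin captures from the egg pool
        cap_a_m = rng.random(R) < y
    else:
        pin = config.captured_allele == "a"
        cap_a_f = np.full(R, pin)
        cap_a_m = np.full(R, pin)

    def add_carrier(state, cats, sex_mask, cap_a, free_pool_freq):
        idx = np.where(sex_mask)[0]
        if not len(idx):
            return
        # remove one resident non-carrier, weighted by counts
        c0 = [i for i, (c, _, _) in enumerate(cats) if c == 0]
        sub = state[idx][:, c0].astype(float)
        sub /= sub.sum(axis=1, keepdims=True)
        pick = (sub.cumsum(axis=1) > rng.random((len(idx), 1))).argmax(axis=1)
        state[idx, np.array(c0)[pick]] -= 1
        free_a = rng.random(len(idx)) < free_pool_freq
        index = {cat: k for k, cat in enumerate(cats)}
        cat_idx = np.array([index[(1, int(a), int(fa))] for a, fa in zip(cap_a[idx], free_a)])
        state[idx, cat_idx] += 1

    if k_f:
        add_carrier(F, cats_f, in_female, cap_a_f, y)
    if k_m:
        add_carrier(M, cats_m, ~in_female, cap_a_m, x)

    active = np.arange(R)
    n_fixed = n_lost = 0
    fix_times: List[int] = []
    gen = 0

    while len(active) and gen < cap:
        gen += 1
        Fa = F[active].astype(float)
        Ma = M[active].astype(float)

        pool_c_f = (Fa @ Gc_f) / N_f if k_f else None
        pool_c_m = (Ma @ Gc_m) / N_m if k_m else None
        pool_p_f = (Fa @ Gp_f) / N_f
        pool_p_m = (Ma @ Gp_m) / N_m

        def offspring_probs(recipe, T, wvec):
            mother = pool_c_f if recipe[0] else pool_p_f
            father = pool_c_m if recipe[1] else pool_p_m
            probs = np.einsum("ri,rj,ijc->rc", mother, father, T)
            probs = probs * wvec
            return probs / probs.sum(axis=1, keepdims=True)

        F_new = _sample_categories(rng, N_f, offspring_probs(recipes["d"], T_d, wvec_f))
        M_new = _sample_categories(rng, N_m, offspring_probs(recipes["s"], T_s, wvec_m))
        F[active] = F_new
        M[active] = M_new

        copies = F_new @ fused_f + M_new @ fused_m
        fixed = copies == n_c
        lost = copies == 0
        n_fixed += int(fixed.sum())
        n_lost += int(lost.sum())
        fix_times.extend([gen] * int(fixed.sum()))
        active = active[~(fixed | lost)]

    return FixationSummary.from_counts(n_fixed, n_lost, len(active),
                                       np.asarray(fix_times, dtype=float), config)
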
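"""Establishment rates of sex chromosome-autosome fusions.

Analytic (diffusion-approximation) predictions for the per-generation rate at
which fusions between each of the four sex chromosome types (X, Y, Z, W) and
an autosome arise and fix in a population with separate sexes.  The
establishment rate of a fusion class is the product of its origination rate
(new fusion mutations per generation, summed over the chromosome copies that
can mutate, through the germline of the sex carrying each copy) and the
fixation probability of a single new copy.

Four selective regimes are covered:

* neutrality (establishment rates reduce to the sex-specific mutation rates),
* direct selection on the fusion itself, with arbitrary dominance,
* female or male meiotic drive, treated as effective direct selection when
  weak, and
* capture of a sexually antagonistic (SA) allele segregating at a linked
  autosomal locus at a two-sex polymorphic equilibrium.

The population is described by the numbers of reproductively successful
females ``N_f`` and males ``N_m`` and by sex-specific per-copy fusion
mutation rates ``mu_f`` and ``mu_m``.  Chromosome-class copy numbers are the
census counts: X has ``2 N_f + N_m`` copies, Y has ``N_m``, Z has
``2 N_m + N_f`` and W has ``N_f``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Optional

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PopulationConfig",
    "ChromosomeClass",
    "DirectSelection",
    "DriveScheme",
    "SALocus",
    "SAEquilibrium",
    "EstablishmentResult",
    "origination_rate",
    "neutral_establishment_rate",
    "neutral_rates",
    "fixation_prob_additive",
    "fixation_prob_general",
    "relative_rate_direct",
    "drive_effective_selection",
    "relative_rate_drive",
    "sa_equilibrium",
    "relative_rate_sa",
    "yw_over_xz_ratio",
]

CLASSES = ("X", "Y", "Z", "W")

# Taylor branch for the neutral limit of the diffusion kernels.
_NEUTRAL_EPS = 1e-12
# Exponent beyond which exp() in the fixation denominators would overflow.
_EXP_GUARD = 700.0

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """Sexed census and mutation parameters.

    Parameters
    ----------
    N_f, N_m
        Numbers of reproductively successful females and males.
    mu_f, mu_m
        Per-chromosome-copy, per-generation fusion mutation rates through the
        female and male germline respectively.
    """

    N_f: int
    N_m: int
    mu_f: float = 0.0
    mu_m: float = 0.0

    def __post_init__(self) -> None:
        if self.N_f < 1 or self.N_m < 1:
            raise ValueError("N_f and N_m must each be at least 1")
        if self.mu_f < 0 or self.mu_m < 0:
            raise ValueError("mutation rates must be non-negative")

    @property
    def reproductive_sex_ratio(self) -> float:
        """Fraction of males among reproductively successful adults."""
        return self.N_m / (self.N_f + self.N_m)


class ChromosomeClass(str, Enum):
    """One of the four sex chromosome types."""

    X = "X"
    Y = "Y"
    Z = "Z"
    W = "W"

    def copies_in_females(self, config: PopulationConfig) -> int:
        return {"X": 2 * config.N_f, "Y": 0, "Z": config.N_f, "W": config.N_f}[self.value]

    def copies_in_males(self, config: PopulationConfig) -> int:
        return {"X": config.N_m, "Y": config.N_m, "Z": 2 * config.N_m, "W": 0}[self.value]

    def copy_count(self, config: PopulationConfig) -> int:
        return self.copies_in_females(config) + self.copies_in_males(config)

    @property
    def female_residence(self) -> float:
        """Long-run fraction of a lineage's generations spent in females.

        These are the stationary fractions of the backward genealogical
        chain fixed by the transmission rules (an X in a male always came
        from his mother; an X in a female came from either parent), and are
        therefore independent of the reproductive sex ratio: X 2/3, Y 0,
        Z 1/3, W 1.  They differ from the census copy shares when
        N_f != N_m.
        """
        return {"X": 2.0 / 3.0, "Y": 0.0, "Z": 1.0 / 3.0, "W": 1.0}[self.value]

    @property
    def male_residence(self) -> float:
        return 1.0 - self.female_residence

    @property
    def male_residence_fraction(self) -> float:
        """Alias for :attr:`male_residence` (X 1/3, Y 1, Z 2/3, W 0)."""
        return self.male_residence

    @property
    def hemizygous(self) -> bool:
        """Y and W fusions are permanently heterozygous with the unfused
        homologue (the neo-X / neo-Z); they never occur in homozygous state."""
        return self.value in ("Y", "W")


@dataclass(frozen=True)
class DirectSelection:
    """Direct fitness effect of the fusion.

    ``s`` is the additive per-copy selection coefficient; genotype fitnesses
    are ``1``, ``1 + 2 h s`` and ``1 + 2 s`` for 0, 1 and 2 fused copies, so
    ``h = 1/2`` is the additive case (heterozygote ``1 + s``).  Optional
    sex-specific coefficients ``s_f`` / ``s_m`` override ``s``.
    """

    s: float = 0.0
    h: float = 0.5
    s_f: Optional[float] = None
    s_m: Optional[float] = None

    def coefficient(self, sex: str) -> float:
        if sex == "f":
            return self.s if self.s_f is None else self.s_f
        return self.s if self.s_m is None else self.s_m

    @property
    def additive(self) -> bool:
        return abs(self.h - 0.5) < 1e-12


@dataclass(frozen=True)
class DriveScheme:
    """Meiotic drive acting on the fused chromosome.

    Heterozygous carriers of the driving sex transmit the fused chromosome
    with relative probability ``1 + f`` (so ``f < 0`` favours unfused
    chromosomes).  Female drive acts at the egg/polar-body decision.
    """

    f: float
    driving_sex: str = "female"

    def __post_init__(self) -> None:
        if self.f <= -1:
            raise ValueError("drive coefficient f must exceed -1")
        if self.driving_sex not in ("female", "male"):
            raise ValueError("driving_sex must be 'female' or 'male'")


@dataclass(frozen=True)
class SALocus:
    """Genotype fitnesses at an autosomal locus with sexually antagonistic
    effects.  Allele ``a`` is conventionally the male-beneficial allele;
    genotype order is (AA, Aa, aa) within each sex.
    """

    w_f_AA: float
    w_f_Aa: float
    w_f_aa: float
    w_m_AA: float
    w_m_Aa: float
    w_m_aa: float

    def __post_init__(self) -> None:
        if min(self.w_f_AA, self.w_f_Aa, self.w_f_aa,
               self.w_m_AA, self.w_m_Aa, self.w_m_aa) <= 0:
            raise ValueError("all fitness values must be positive")

    def female_fitness(self, n_a: int) -> float:
        return (self.w_f_AA, self.w_f_Aa, self.w_f_aa)[n_a]

    def male_fitness(self, n_a: int) -> float:
        return (self.w_m_AA, self.w_m_Aa, self.w_m_aa)[n_a]

    @classmethod
    def symmetric(cls, s_hom: float = 0.10, s_het: float = 0.09) -> "SALocus":
        """Fully sex-symmetric antagonism: the favoured allele in each sex has
        advantage ``s_hom`` when homozygous and ``s_het`` when heterozygous
        (default 10% / 9%)."""
        return cls(
            w_f_AA=1.0 + s_hom, w_f_Aa=1.0 + s_het, w_f_aa=1.0,
            w_m_AA=1.0, w_m_Aa=1.0 + s_het, w_m_aa=1.0 + s_hom,
        )


@dataclass(frozen=True)
class SAEquilibrium:
    """Equilibrium allele frequencies of the male-beneficial allele ``a``
    among eggs (``x``) and sperm (``y``); ``polymorphic`` is False when the
    recursion converges to a boundary (no protected polymorphism)."""

    x_egg: float
    y_sperm: float
    polymorphic: bool
    iterations: int


@dataclass(frozen=True)
class EstablishmentResult:
    """Per-class origination rates, fixation probabilities, establishment
    rates and rates relative to the X-A value."""

    origination_rate: Dict[str, float]
    fixation_prob: Dict[str, float]
    establishment_rate: Dict[str, float]
    relative_rate: Dict[str, float]

    @classmethod
    def from_components(cls, orig: Dict[str, float], fix: Dict[str, float]) -> "EstablishmentResult":
        est = {c: orig[c] * fix[c] for c in CLASSES}
        ref = est["X"]
        rel = {c: (est[c] / ref if ref > 0 else math.nan) for c in CLASSES}
        return cls(origination_rate=dict(orig), fixation_prob=dict(fix),
                   establishment_rate=est, relative_rate=rel)


# ---------------------------------------------------------------------------
# Origination and neutral establishment
# ---------------------------------------------------------------------------


def origination_rate(chrom: ChromosomeClass, config: PopulationConfig) -> float:
    """Expected number of new fusions of this class arising per generation.

    Each copy mutates through the germline of the sex that carries it, so
    X: 2 N_f mu_f + N_m mu_m, Y: N_m mu_m, Z: 2 N_m mu_m + N_f mu_f,
    W: N_f mu_f.
    """
    chrom = ChromosomeClass(chrom)
    return (chrom.copies_in_females(config) * config.mu_f
            + chrom.copies_in_males(config) * config.mu_m)


def neutral_establishment_rate(chrom: ChromosomeClass, config: PopulationConfig) -> float:
    """Neutral establishment rate = origination rate x 1/copy_count.

    Independent of the census sizes (and hence of sex-ratio bias among
    breeders): at an unbiased sex ratio the four rates are
    (2 mu_f + mu_m)/3, mu_m, (2 mu_m + mu_f)/3 and mu_f for X, Y, Z, W.
    """
    if config.mu_f + config.mu_m <= 0:
        raise ValueError("mu_f + mu_m must be positive for establishment-rate queries")
    chrom = ChromosomeClass(chrom)
    return origination_rate(chrom, config) / chrom.copy_count(config)


def neutral_rates(config: PopulationConfig) -> EstablishmentResult:
    orig = {c: origination_rate(ChromosomeClass(c), config) for c in CLASSES}
    fix = {c: 1.0 / ChromosomeClass(c).copy_count(config) for c in CLASSES}
    if config.mu_f + config.mu_m <= 0:
        raise ValueError("mu_f + mu_m must be positive for establishment-rate queries")
    return EstablishmentResult.from_components(orig, fix)


# ---------------------------------------------------------------------------
# Fixation probabilities
# ---------------------------------------------------------------------------


def fixation_prob_additive(s: float, n_c: int) -> float:
    """Diffusion fixation probability of one new copy under additive
    per-copy selection ``s`` in a class with ``n_c`` census copies:

        u = (1 - exp(-2 s)) / (1 - exp(-2 n_c s))

    with the neutral limit 1/n_c taken explicitly, and overflow-guarded
    asymptotics for large ``|2 n_c s|``.
    """
    if n_c < 1:
        raise ValueError("copy number must be at least 1")
    z = 2.0 * n_c * s
    if abs(z) < _NEUTRAL_EPS:
        # Taylor: u -> (1/n_c) * (1 - s (n_c - 1) / ... ), leading order 1/n_c
        return 1.0 / n_c
    if z > _EXP_GUARD:  # strongly favoured: denominator ~ 1
        return -math.expm1(-2.0 * s)
    if z < -_EXP_GUARD:  # strongly disfavoured: u ~ expm1(-2s) * exp(z) -> log space
        # u = (1 - e^{-2s}) / (1 - e^{-z'}) with z' = -z large positive
        # = -expm1(-2s) * exp(z) / (exp(z) - 1) ~ -expm1(-2s) * exp(z)
        log_u = math.log(-math.expm1(-2.0 * s)) + z if s > 0 else \
            math.log(math.expm1(-2.0 * s)) + z
        # s < 0 here (z < 0 and n_c > 0 means s < 0); expm1(-2s) > 0
        return math.exp(log_u) if log_u > -745 else 0.0
    return math.expm1(-2.0 * s) / math.expm1(-z)


def _weak_selection_fixation(s: float, n_c: int) -> float:
    """Weak-selection (branching-process numerator) fixation kernel

        u = 2 s / (1 - exp(-2 n_c s)),   u(0) = 1/n_c.

    n_c * u depends on n_c and s only through the product n_c * s, which makes
    the origination/fixation compensation exact.  Used by the sexually
    antagonistic path, where the per-generation coefficient differs between
    chromosome classes (see docs/methods.md).
    """
    z = 2.0 * n_c * s
    if abs(z) < _NEUTRAL_EPS:
        return 1.0 / n_c
    if z > _EXP_GUARD:
        return 2.0 * s
    if z < -_EXP_GUARD:
        return 2.0 * s * math.exp(z) / (math.exp(z) - 1.0) if z > -745 else 0.0
    return -2.0 * s / math.expm1(-z)


def _class_selection(chrom: ChromosomeClass, selection: DirectSelection,
                     config: PopulationConfig) -> float:
    """Sex-time-weighted additive coefficient experienced by a class."""
    return (chrom.female_residence * selection.coefficient("f")
            + chrom.male_residence * selection.coefficient("m"))


def fixation_prob_general(chrom: ChromosomeClass, selection: DirectSelection,
                          config: PopulationConfig) -> float:
    """Fixation probability with arbitrary dominance ``h``.

    Genotype fitnesses are 1, 1 + 2 h s, 1 + 2 s.  Hemizygous classes (Y, W)
    are permanently heterozygous with their unfused partner, so they
    experience the heterozygote effect ``2 h s`` throughout and reduce to the
    additive kernel with that coefficient.  For X and Z the Kimura fixation
    probability is evaluated by quadrature, weighting the diploid-dominance
    drift term by the class's female/male residence fractions (the class is
    hemizygous while resident in the single-copy sex).
    """
    chrom = ChromosomeClass(chrom)
    n_c = chrom.copy_count(config)
    h = selection.h
    if selection.additive:
        return fixation_prob_additive(_class_selection(chrom, selection, config), n_c)
    if chrom.hemizygous:
        sex = "m" if chrom is ChromosomeClass.Y else "f"
        return fixation_prob_additive(2.0 * h * selection.coefficient(sex), n_c)

    # Residence fractions: diploid dominance applies in the two-copy sex,
    # constant heterozygote effect in the one-copy sex.
    if chrom is ChromosomeClass.X:
        fr_dip = chrom.female_residence
        s_dip = selection.coefficient("f")
        s_hemi = selection.coefficient("m")
    else:  # Z
        fr_dip = chrom.male_residence
        s_dip = selection.coefficient("m")
        s_hemi = selection.coefficient("f")
    fr_hemi = 1.0 - fr_dip

    # G(x) = exp(-psi(x)) with psi'(x) = 2 M(x) n_c / (x (1 - x)):
    #   M(x) = fr_dip * 2 s x(1-x)(h + (1-2h) x) + fr_hemi * 2 h s x(1-x)
    def psi(x: float) -> float:
        return 2.0 * n_c * (fr_dip * 2.0 * s_dip * (h * x + (1.0 - 2.0 * h) * x * x / 2.0)
                            + fr_hemi * 2.0 * h * s_hemi * x)

    # Shift by psi at 0 for numerical stability; integrand <= 1 when psi grows.
    pmax = max(psi(x) for x in np.linspace(0.0, 1.0, 201))
    pmin = min(psi(x) for x in np.linspace(0.0, 1.0, 201))
    shift = (pmax + pmin) / 2.0

    def integrand(x: float) -> float:
        return math.exp(-(psi(x) - shift))

    p0 = 1.0 / n_c
    num, num_err = quad(integrand, 0.0, p0, limit=200)
    den, den_err = quad(integrand, 0.0, 1.0, limit=200)
    if den <= 0 or not math.isfinite(num / den):
        raise ArithmeticError("fixation-probability quadrature did not converge")
    if den_err > 1e-8 * den:
        warnings.warn("fixation-probability quadrature has low accuracy", RuntimeWarning)
    return num / den


# ---------------------------------------------------------------------------
# Direct selection
# ---------------------------------------------------------------------------


def relative_rate_direct(selection: DirectSelection,
                         config: PopulationConfig) -> EstablishmentResult:
    """Establishment rates under direct selection on the fusion.

    With N_f = N_m = N_sex and mu_f = mu_m, the additive Y/X (and W/X) ratio
    equals (1 + exp(-4 s N_sex) + exp(-2 s N_sex)) / 3.
    """
    orig = {c: origination_rate(ChromosomeClass(c), config) for c in CLASSES}
    fix = {}
    for c in CLASSES:
        chrom = ChromosomeClass(c)
        if selection.additive:
            fix[c] = fixation_prob_additive(_class_selection(chrom, selection, config),
                                            chrom.copy_count(config))
        else:
            fix[c] = fixation_prob_general(chrom, selection, config)
    return EstablishmentResult.from_components(orig, fix)


def yw_over_xz_ratio(s: float, n_sex: int) -> float:
    """Closed-form additive Y/X (= W/Z) establishment ratio at unbiased sex
    ratio and mutation rates: (1 + e^{-4 s N} + e^{-2 s N}) / 3."""
    return (1.0 + math.exp(-4.0 * s * n_sex) + math.exp(-2.0 * s * n_sex)) / 3.0


# ---------------------------------------------------------------------------
# Meiotic drive
# ---------------------------------------------------------------------------

#: Weak-drive validity bound; beyond this the drive-as-selection mapping is a
#: poor approximation and the Wright-Fisher simulator should be used instead.
WEAK_DRIVE_LIMIT = 0.05


def drive_effective_selection(chrom: ChromosomeClass, drive: DriveScheme,
                              config: Optional[PopulationConfig] = None) -> float:
    """Effective additive selection coefficient for weak meiotic drive.

    Drive in heterozygotes of the driving sex gives the fused chromosome a
    per-generation transmission advantage ``f`` while resident in that sex, so
    the sex-averaged effective coefficient is ``f`` times the class's
    lineage time fraction in the driving sex: female drive gives s_X = 2f/3,
    s_Y = 0, s_Z = f/3, s_W = f; male drive is the mirror (s_X = f/3,
    s_Y = f, s_Z = 2f/3, s_W = 0).
    """
    chrom = ChromosomeClass(chrom)
    if abs(drive.f) > WEAK_DRIVE_LIMIT:
        warnings.warn(
            f"|f| = {abs(drive.f):.3g} exceeds the weak-drive regime "
            f"(|f| <= {WEAK_DRIVE_LIMIT}); use the Wright-Fisher simulator "
            "for exact drive dynamics", RuntimeWarning)
    if drive.driving_sex == "female":
        return drive.f * chrom.female_residence
    return drive.f * chrom.male_residence


def relative_rate_drive(drive: DriveScheme,
                        config: PopulationConfig) -> EstablishmentResult:
    """Establishment rates under weak meiotic drive.

    With female drive, f < 0 and an unbiased configuration the rates order
    strictly Y > W > Z > X (reversed for f > 0); with male drive favouring
    fusions, Z-A fusions establish even faster than Y-A fusions.
    """
    orig = {c: origination_rate(ChromosomeClass(c), config) for c in CLASSES}
    fix = {}
    for c in CLASSES:
        chrom = ChromosomeClass(c)
        s_eff = drive_effective_selection(chrom, drive, config)
        fix[c] = fixation_prob_additive(s_eff, chrom.copy_count(config))
    return EstablishmentResult.from_components(orig, fix)


# ---------------------------------------------------------------------------
# Sexually antagonistic selection
# ---------------------------------------------------------------------------


def _sa_step(x: float, y: float, locus: SALocus) -> tuple[float, float]:
    """One generation of the exact two-sex genotype-frequency recursion.

    ``x`` and ``y`` are the frequencies of allele ``a`` among eggs and sperm.
    Offspring genotypes form by random union; sex-specific viabilities apply;
    returns next-generation gamete frequencies (eggs, sperm).
    """
    g_aa = x * y
    g_Aa = x * (1.0 - y) + (1.0 - x) * y
    g_AA = (1.0 - x) * (1.0 - y)
    wf = (g_AA * locus.w_f_AA, g_Aa * locus.w_f_Aa, g_aa * locus.w_f_aa)
    wm = (g_AA * locus.w_m_AA, g_Aa * locus.w_m_Aa, g_aa * locus.w_m_aa)
    x1 = (wf[2] + 0.5 * wf[1]) / sum(wf)
    y1 = (wm[2] + 0.5 * wm[1]) / sum(wm)
    return x1, y1


def sa_equilibrium(locus: SALocus, tol: float = 1e-14,
                   max_iter: int = 200_000) -> SAEquilibrium:
    """Internal equilibrium of the two-sex one-locus viability recursion.

    Iterates the exact genotype-frequency recursion from an interior start
    until gamete frequencies converge.  Convergence to a boundary (allele
    frequency within 1e-9 of 0 or 1) is flagged as absence of a protected
    polymorphism rather than raised.
    """
    x, y = 0.5, 0.5
    it = 0
    for it in range(1, max_iter + 1):
        x1, y1 = _sa_step(x, y, locus)
        if abs(x1 - x) < tol and abs(y1 - y) < tol:
            x, y = x1, y1
            break
        x, y = x1, y1
    pbar = (x + y) / 2.0
    polymorphic = 1e-9 < pbar < 1.0 - 1e-9
    return SAEquilibrium(x_egg=x, y_sperm=y, polymorphic=polymorphic, iterations=it)


def _sa_invasion_coefficients(locus: SALocus, p: float) -> Dict[str, Dict[str, float]]:
    """Per-sex invasion coefficients of a fused haplotype carrying allele
    ``i``: the marginal fitness of a rare fused chromosome whose attached
    allele is paired with a random allele (frequency ``p`` of allele a) from
    the population gamete pool, relative to the sex's mean fitness at the
    Hardy-Weinberg equilibrium background.

    The analytic treatment pools eggs and sperm into a single gamete
    frequency; the egg/sperm split at equilibrium is an O(s^2) refinement
    carried only by the Wright-Fisher simulator.
    """
    g = ((1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p)
    wbar_f = sum(gi * locus.female_fitness(i) for i, gi in enumerate(g))
    wbar_m = sum(gi * locus.male_fitness(i) for i, gi in enumerate(g))

    def s_in_sex(sex: str) -> Dict[str, float]:
        fit = locus.female_fitness if sex == "f" else locus.male_fitness
        wbar = wbar_f if sex == "f" else wbar_m
        out = {}
        for allele, n_att in (("A", 0), ("a", 1)):
            w = p * fit(n_att + 1) + (1.0 - p) * fit(n_att)
            out[allele] = w / wbar - 1.0
        return out

    s_f, s_m = s_in_sex("f"), s_in_sex("m")
    return {"X": {"f": s_f, "m": s_m}, "Y": {"m": s_m},
            "Z": {"f": s_f, "m": s_m}, "W": {"f": s_f}}


def relative_rate_sa(locus: SALocus, config: PopulationConfig,
                     eq: Optional[SAEquilibrium] = None) -> EstablishmentResult:
    """Establishment rates of fusions that capture a sexually antagonistic
    allele at a polymorphic equilibrium.

    A new fusion captures allele ``a`` with probability equal to its
    equilibrium frequency; once fused the locus is completely linked to the
    sex-determining region, so the fused haplotype evolves under the
    sex-time-weighted invasion coefficient of its captured allele.  Fixation
    uses the weak-selection kernel so that the exact origination/fixation
    compensation holds: with an unbiased configuration the four establishment
    rates are equal, and the Y-A rate exceeds the X-A rate exactly when
    mu_m * N_m > mu_f * N_f.

    Raises ``ValueError`` when the locus admits no protected polymorphism.
    """
    if eq is None:
        eq = sa_equilibrium(locus)
    if not eq.polymorphic:
        raise ValueError("SA locus admits no protected polymorphism; "
                         "establishment rates under SA capture are undefined")
    p_a = (eq.x_egg + eq.y_sperm) / 2.0
    inv = _sa_invasion_coefficients(locus, p_a)

    orig: Dict[str, float] = {}
    est: Dict[str, float] = {}
    fix: Dict[str, float] = {}
    for c in CLASSES:
        chrom = ChromosomeClass(c)
        n_c = chrom.copy_count(config)
        fr_f = chrom.female_residence
        fr_m = chrom.male_residence
        coeffs = inv[c]

        def s_class(allele: str) -> float:
            s = 0.0
            if "f" in coeffs:
                s += fr_f * coeffs["f"][allele]
            if "m" in coeffs:
                s += fr_m * coeffs["m"][allele]
            return s

        total_orig = origination_rate(chrom, config)
        rate = 0.0
        for allele, p in (("a", p_a), ("A", 1.0 - p_a)):
            u = _weak_selection_fixation(s_class(allele), n_c)
            rate += total_orig * p * u
        orig[c] = total_orig
        est[c] = rate
        fix[c] = rate / total_orig if total_orig > 0 else math.nan

    ref = est["X"]
    rel = {c: (est[c] / ref if ref > 0 else math.nan) for c in CLASSES}
    return EstablishmentResult(origination_rate=orig, fixation_prob=fix,
                               establishment_rate=est, relative_rate=rel)
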
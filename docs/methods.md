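# Methods

`karyofuse` asks why fusions between sex chromosomes and autosomes establish
at such different rates depending on which chromosome (X, Y, Z or W) is
involved, and provides the machinery to test explanations: analytic
population-genetic predictions, an exact forward simulator to arbitrate
them, and a phylogenetic comparative pipeline exercised on synthetic data
with known ground truth.

## Establishment-rate theory

The establishment rate of a fusion class is the product of its origination
rate and the fixation probability of a single new copy.

**Origination.** Each chromosome copy can fuse during gametogenesis of the
sex that carries it, with per-copy rates μ_f (female germline) and μ_m
(male germline). With N_f breeding females and N_m breeding males the
origination rates are 2N_f μ_f + N_m μ_m (X), N_m μ_m (Y), 2N_m μ_m + N_f μ_f
(Z) and N_f μ_f (W).

**Neutral fixation.** A neutral copy fixes with probability 1/n_c, where
n_c is the class's census copy number. Establishment rates then reduce to
mutation-rate combinations — (2μ_f + μ_m)/3, μ_m, (2μ_m + μ_f)/3 and μ_f
for X, Y, Z, W — independent of population size and of sex-ratio bias among
breeders. With male-limited mutation the Z-A rate is exactly 2/3 of the
Y-A rate, and it can never fall below 2/3 of it for any μ_f ≥ 0.

**Direct selection.** For an additive fusion with per-copy effect s
(genotype fitnesses 1, 1+2hs, 1+2s; h = 1/2 additive) we use the Kimura
diffusion fixation probability with the census copy number,

    u(s, n_c) = (1 − e^(−2s)) / (1 − e^(−2 n_c s)),

evaluated through `expm1` with an explicit neutral branch at |2 n_c s| <
1e−12 and log-space asymptotics when the exponent would overflow. At
N_f = N_m = N and equal mutation rates the Y/X (and W/X) establishment
ratio collapses to the closed form (1 + e^(−4sN) + e^(−2sN))/3.

**Lineage time fractions.** When selection (or drive) is sex-specific, the
class's effective coefficient is the time-average over the sexes. The
relevant weights are the stationary fractions of the *backward genealogical
chain*, which are fixed by the transmission rules and therefore independent
of the reproductive sex ratio: an X spends 2/3 of its generations in
females and 1/3 in males whether or not N_f = N_m (an X in a male always
came from his mother; an X in a female came from either parent with equal
probability). Using census copy *shares* instead would make the sexually
antagonistic predictions below depend on the sex ratio in a way that breaks
their exact structure. Census copy numbers are retained for origination
and for the drift scale in the diffusion; under strongly biased sex ratios
the census drift scale is an approximation (variance-effective sizes
differ), and the Wright–Fisher simulator is the arbiter there.

**Arbitrary dominance.** For X and Z the fixation probability is computed
by numerical quadrature of the diffusion with a drift term that mixes
diploid dominance (while resident in the two-copy sex) and the constant
heterozygote effect 2hs (while hemizygous), weighted by the lineage time
fractions. Y-A and W-A fusions are permanently heterozygous with their
unfused partner (the neo-X/neo-Z), so they experience 2hs in every
generation and reduce to the additive kernel with that coefficient — which
is why underdominant fusions can never favour the Y: the heterozygote
penalty never ends for a Y-A fusion.

**Meiotic drive.** Heterozygous carriers of the driving sex transmit the
fused chromosome with relative probability 1+f (female drive acts at the
egg/polar-body decision, so the transmission probability is (1+f)/2 against
(1−f)/2). Weak drive is equivalent to direct selection with coefficient
f times the class's time fraction in the driving sex: female drive gives
s_X = 2f/3, s_Y = 0, s_Z = f/3, s_W = f, and male drive the mirror image.
The mapping is used only for |f| ≤ 0.05 (a warning is issued beyond);
strong drive belongs to the simulator.

**Sexually antagonistic capture.** An autosomal locus segregates for a
male-beneficial allele a and a female-beneficial allele A at a two-sex
viability equilibrium, found by iterating the exact genotype-frequency
recursion (tolerance 1e−14; convergence to a boundary is flagged as
absence of a protected polymorphism, not raised). A new fusion captures
one allele in proportion to its frequency; once fused, the locus is in
complete linkage with the sex-determining region. The fused haplotype's
invasion coefficient per sex is its marginal viability against a random
partner allele, relative to the sex's mean fitness; the class coefficient
is the time-fraction-weighted average.

Two deliberate choices make the analytic structure exact rather than
approximate-looking:

1. *Pooled gamete frequency.* The analytic treatment summarises the
   equilibrium by the pooled frequency p = (x_eggs + y_sperm)/2 with a
   Hardy–Weinberg genotype background. Selection splits egg and sperm
   frequencies at O(s); carrying that split through the capture and
   invasion bookkeeping introduces O(s²) class asymmetries (~3% at a 10%
   fitness scheme) that are artefacts of mixing orders. The full two-pool
   dynamics live in the simulator.
2. *Weak-selection fixation kernel.* The SA path uses
   u = 2s/(1 − e^(−2 n_c s)), the branching-process numerator, so that
   n_c·u depends on n_c and s only through n_c·s. With this kernel the
   origination deficit of the Y and W (fewer copies) cancels their
   selective advantage (always resident in one sex) *exactly*: at an
   unbiased configuration all four establishment rates are equal to
   machine precision, and the Y-A rate exceeds the X-A rate precisely when
   μ_m N_m > μ_f N_f. The exact-numerator kernel would leave O(s) residuals
   that contradict the analytic equal-rates result it is meant to express.
   (For direct selection and drive the exact-numerator kernel is kept: the
   per-copy coefficient is shared across classes there, so the choice
   cancels from every ratio.)

Both statements are leading-order in selection strength. The forward
simulator shows that at a 10%-advantage scheme the exact dynamics favour
X/Z fusions by ~20–30% through frequency-dependent marginal fitness once
the fused haplotype leaves the rare-invader regime; at a 2% scheme the
deviation is below Monte-Carlo resolution. The equal-rates prediction
should therefore be read as a weak-selection statement.

## Wright–Fisher simulator

The simulator is the brute-force arbiter for every analytic claim:
discrete generations; N_f mothers and N_m fathers sampled multinomially
from the offspring pool each generation; viability selection on offspring
genotypes; drive applied at gametogenesis. Fusion genotypes are tracked as
per-sex category counts (fused-copy number, and for the SA variant also
the attached and free alleles at the linked locus), so hundreds of
thousands of replicates run vectorised. A replicate ends at fixation,
loss, or a generation cap of 100 × n_c; capped runs are reported
separately, never coerced into losses.

Drive in two-copy heterozygotes is the transmission distortion
(1+f)/2 : (1−f)/2; for hemizygous carriers (fused Y in a male, fused W in
a female) the drive acts as a (1+f) weight on the carrier's class-bearing
gametes — their same-sex offspring all inherit the fusion, so drive there
is fertility-like. A consequence checked in the tests: the
f ↔ −f mirror symmetry under exchange of fused/unfused labels is exact for
the two-copy classes but not for the hemizygous parameterisation.

SA-capture runs initialise residents at the deterministic equilibrium,
build the carrier's free allele from the opposite gamete pool, and keep
complete linkage between the fused chromosome and its attached allele
(free recombination otherwise).

## Phylogenetic comparative machinery

Karyotype evolution is modelled as a continuous-time Markov chain on
either four states (XY, XY-fused, ZW, ZW-fused) or six (distinguishing
which chromosome fused: X₁X₂Y = Y-A, XY₁Y₂ = X-A, Z₁Z₂W = W-A,
ZW₁W₂ = Z-A). Transitions are named parameters with a sharing map, so
reduced models (e.g. a common fission rate) are declared, fitted and
compared by likelihood-ratio tests.

Likelihoods use Felsenstein pruning with per-branch matrix exponentials
(eigendecomposition with a conditioning check, scaling-and-squaring
fallback; per-node rescaling guards underflow; zero-length branches are
identity maps). Root states are weighted equally by default, with
stationary and FitzJohn options; outputs record which was used because the
choice is not innocuous for asymmetric models. Ambiguous or missing tips
get uniform rows (the standard Mk convention). Homomorphic and
heteromorphic sex chromosomes are not distinguished; heterogamety turnover
is allowed between unfused states by default, with a flag to allow it
between fused states in the four-state space.

ML fitting is bounded multi-start L-BFGS-B on log rates. The
likelihood-ratio test against a parameter-sharing reduction uses the χ²
reference with df equal to the number of parameters merged; that reference
is asymptotic, and calibration experiments show the test is markedly
*conservative* when the merged rates are informed by only a handful of
events (type-I error ~0.01–0.02 at nominal 0.05 with ≲10 fission events
per system), approaching nominal (~0.05–0.07) once each system carries
tens of events. Model-reduction decisions on event-poor data are therefore
biased toward the reduced model, which is the safe direction but worth
knowing. The MCMC places
independent exponential priors (mean 0.05) on every rate and updates each
parameter per sweep by univariate slice sampling (stepping-out and
shrinkage); the headline statistic is the posterior of the fusion-rate
difference q_XY.XYF − q_ZW.ZWF, summarised by the fraction of mass above
zero and a 95% quantile credibility interval. Reference settings are
50,000 sweeps with 10,000 burn-in; the packaged reduced settings (4,000 /
800, and 300–500-tip trees) keep a full run on one CPU in minutes and are
used by the tests and the acceptance script. Prior-only chains (flat
likelihood) are part of the test suite and must recover the prior mean.

Species tables are aligned to trees by exact name matching, then by genus
substitution: an unmatched tip may stand in for an unmatched congener from
the table as long as the genus keeps at most two representatives; leftover
tips are pruned, and every substitution and pruning is reported.

## Synthetic data

Trees are constant-rate birth–death simulations conditioned on the number
of surviving tips (extinct subtrees pruned, restart on total extinction);
the process stops the first time the extant count reaches the target and
pendant edges are extended by the waiting time to the next (unrealised)
event, giving the closed-form pure-birth expected height
(1/λ)(Σ_{k=2}^{n−1} 1/k + 1/n) that the tests verify. Genera are
contiguous blocks of tips in traversal order with geometric sizes — a
stylised choice that makes genus substitution phylogenetically plausible.

Character histories draw the root state from the chain's stationary
distribution — the natural assumption for a clade old enough to be at
equilibrium. (An equal-weight root draw would start a quarter of all
histories in the near-impossible fused-ZW state, whose slow decay then
dominates whole trees.) Default generating rates are q_XY.XYF = 0.1
versus q_ZW.ZWF = 0.005 (the
20-fold contrast used in the recovery experiments), shared fissions at
0.1, and symmetric turnover at 0.15. With these, roughly half of XY-system
tips and ~5% of ZW-system tips are fused at stationarity, and both
heterogamety systems are typically well represented on trees of height
log(n) — the prevalence structure of the vertebrate survey data the
generator stands in for. Because deep turnover is phylogenetically
correlated, single trees can still be dominated by one system; dataset
generation optionally redraws histories until each system holds a minimum
tip fraction, mirroring the empirical design of analysing clades that
segregate for many origins of both systems. What passing on such data does
*not* show: robustness to state-dependent diversification, correlated
missingness, or misdiagnosed karyotypes, none of which the generator
emulates.

## Numerical and design notes

- Diffusion kernels: `expm1` throughout; neutral branch below |2 n_c s| =
  1e−12; log-space tails beyond exponent 700.
- SA equilibrium: fixed-point iteration, tolerance 1e−14, cap 200,000
  iterations; boundary within 1e−9 ⇒ no polymorphism.
- Quadrature (arbitrary dominance): adaptive `quad` on a shifted
  integrand; convergence failure raises, low accuracy warns.
- Matrix exponentials: eigendecomposition accepted only when the
  eigenvector condition number is below 1e8 and rows renormalise to 1
  within 1e−8; otherwise scipy's `expm` per branch.
- LRT: a statistic below −1e−6 triggers a refit of the full model from the
  reduced optimum; the statistic is clamped at 0.
- Fisher's exact test: two-sided by probability ordering with a 1e−7
  relative tie tolerance, log-gamma factorials.
- The packaged survey fixture ships as per-group counts transcribed from
  the published table (footnote exclusions as flag columns); the
  species-level expansion uses synthetic placeholder names and is the exact
  inverse of the tabulation, which the tests exploit as a round trip.
- Sidedness of the published Fisher bounds is not stated in the source;
  both one- and two-sided versions satisfy the printed inequality, and the
  two-sided test is the default.

## Known limitations

- The analytic SA and drive results are weak-selection/weak-drive
  approximations; the simulator is authoritative outside those regimes.
- The census drift scale under strongly biased sex ratios (|N_m/(N_f+N_m)
  − 1/2| > 0.2) has not been validated against the simulator and the
  analytic path should be treated as qualitative there.
- The Mk machinery ignores state-dependent diversification; if fused
  lineages speciate or go extinct at different rates, rate contrasts are
  confounded.
- Four-state fused tips are exported as Y-A (XY) and W-A (ZW) in species
  tables — the four-state space cannot resolve the fused partner, and
  those are the empirically dominant classes.
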
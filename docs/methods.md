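# Methods

## Reactor O₂ mass balance

At steady state the net specific O₂ production rate qO₂ (mmol O₂ h⁻¹
g_AFDW⁻¹) follows from a balance over the liquid control volume:

    qO₂ · x = D([O₂] − [O₂_in]) + k_La([O₂] − k_H·pO₂_in)

The right-hand side is the sum of the net convective export of dissolved O₂
and the net stripping flux to the sparge gas. The balance is sometimes
written with both differences reversed, which makes the right-hand side
negative for a net O₂ producer sparged with O₂-free gas; `photoacclim` uses
the production-positive arrangement above so that photosynthesis yields
positive qO₂. Assumptions: well-mixed liquid, constant volume, steady
state, and a lumped transfer coefficient valid across conditions.

Canonical units are h⁻¹, µM, g AFDW L⁻¹, and mmol h⁻¹ g⁻¹. `GasLiquidParams`
accepts a per-minute k_La with an explicit unit tag (`kla_unit="per_minute"`)
and converts once at construction; defaults are k_La = 0.83 min⁻¹
(49.8 h⁻¹), k_H = 1.08 mM atm⁻¹, O₂-free in-gas and inflow medium
([O₂_in] = 0 µM, overridable). Biomass is put on a carbon-mole basis with
24.59 g AFDW per C-mol.

The photosynthetic quotient Q (Cmmol biomass per mmol O₂) is estimated as
the per-regime ordinary-least-squares slope of q_X on qO₂ **with**
intercept: the light-limited and light-saturated branches are separate
operating lines, and forcing them through the origin is an extra assumption
(a no-intercept option exists). Regimes with fewer than two points or zero
qO₂ variance are flagged, not fitted.

Steady state is declared when every monitored channel (OD₇₃₀, pH, dissolved
O₂) varies by at most 3 % — inclusive, relative variation defined as
|Δ|/pair mean — between consecutive measurements, and at least five reactor
residence times have elapsed.

## Light-response model

Growth or photosynthesis rate versus incident irradiance is fit with a
Platt-type curve in which the inhibition exponent is written directly as an
irradiance threshold:

    R(I_i) = R_max · (1 − exp(−I_i/I_k)) · exp(−I_i/β)

Both exponents are ratios of irradiances; β has the same units as I_i and
I_k, and β → ∞ recovers the Webb saturating exponential. Derived
quantities: initial slope α = R_max/I_k, and for finite β an interior
maximum at I* = I_k·ln(1 + β/I_k) (obtained by setting dR/dI_i = 0).

Fitting minimises Σ wᵢ(Rᵢ − model)² with wᵢ = 1/sdᵢ² when replicate
standard deviations are given, else unit weights. The optimiser is
multi-start bounded Levenberg–Marquardt-type least squares (≥5 starts:
R_max⁰ = max R, I_k⁰ = irradiance nearest half-max, β⁰ ∈ {2, 10}·max I_i,
plus jittered restarts from a fixed seed), with tight tolerances so
zero-residual data recover generating parameters to ≈1e-6 relative error.
Standard errors come from the Gauss–Newton covariance at the optimum.

Because the saturating model is nested in the full model, whether the data
support finite β is decided by an extra-sum-of-squares F-test at α = 0.05
(`model="auto"`): finite β is kept only when it reduces the weighted SSE
significantly. This avoids assigning spurious photoinhibition to saturating
data, at the cost of the test's α-level rate of false inhibition calls —
when the generating family is known (as in simulation studies) fitting the
matching submodel directly is preferable, and the parameter-recovery checks
do so. Model selection under `auto` occasionally produces strongly
correlated (R_max, β) excursions on noisy saturating data; the median fit
is unaffected but mean-bias summaries over many replicates should use the
matched submodel.

Regime classification around I_k uses a fractional half-width δ
(default 0.25): I_i < (1−δ)I_k is light-limited, I_i > (1+δ)I_k is
light-saturated, the band between is transitional. No numeric width for
"near I_k" is standard; δ is exposed everywhere it is used.

## PAM fluorometry

rETR = PAR·(F_m′ − F)/F_m′; F > F_m′ yields a negative value that is
flagged but preserved (clamping would hide instrument anomalies). Rapid
light curves are fit with the saturating (β = ∞) light-response submodel;
rETR_max is the fitted asymptote (the maximum observed point is also
reported) and α_r = R_max/I_k its initial slope. F_v/F_m = (F_m − F_o)/F_m.

The post-illumination fluorescence rise is quantified as the OLS slope of F
versus time over the first 10 s (configurable) of the 30-s dark phase of
the four-step protocol (200-ms saturating pulse, 5 s far-red, 15 s actinic,
30 s dark); the rise reflects plastoquinone reduction by reductant
accumulated in the light and serves as a relative cyclic-electron-flow
proxy. It is a slope in fluorescence units s⁻¹, not a normalised amplitude.
Phase labels are required input rather than inferred from the light
program — unambiguous and testable.

## Expression clustering

Genes in the bottom 20 % of expression (by rank, ties broken by gene
identifier) at **every** condition are removed (policy `all`; `any` is
available). Retained genes are transformed log₂(RPKM + 1) — the pseudocount
is configurable — and z-scored per gene with the population standard
deviation, so each row has exactly mean 0 and sd 1; genes constant across
conditions are excluded and reported rather than silently zeroed.

Clustering is agglomerative with Euclidean distance and average linkage
(both configurable), cut to exactly k clusters; rows are processed in
gene-identifier order and cluster ids renumbered by size, making the result
deterministic and permutation-equivariant. The default is k = 6 followed by
a merge of clusters whose eigengenes correlate at r > 0.8, reporting the
major modules (typically four); both the fine and merged partitions are
available, since a six-profile cut and a four-module summary are different
views of the same tree.

The eigengene of a cluster is the first right singular vector of its
genes × conditions submatrix (unit norm), with sign chosen to correlate
non-negatively with the cluster's mean profile; variance explained is the
leading squared singular value over the total. Eigengene–phenotype
alignment is quantified by Pearson correlation against a per-condition
phenotype such as μ.

## Enrichment

For each (level, category) with at least one member in a cluster, a 2×2
table over the gene universe is tested with the one-sided (greater) Fisher
exact test; reported per row are the percent of cluster genes in the
category and the ratio of that percent to the category's percent in the
universe. The default universe is the post-filter expressed gene set, not
the whole annotated genome, because that is the population the clusters
partition; the annotation-wide universe is an option. Raw P < 0.05 flags
significance by default — matching how such tables are usually reported —
with an optional Benjamini–Hochberg column computed per level. Genes
carrying several categories at one level are counted once per category.

## Morphometrics

Cells are prolate spheroids with minor-axis diameter a (two equal
equatorial diameters) and major-axis diameter b:

    V = (π/6)·a²·b      (semi-axes a/2, a/2, b/2)

The ellipsoid formula is sometimes printed with the (4/3)π prefactor while
a and b are still defined as diameters; that form is 8× larger and is
available as `mode="as_printed"`, but the diameter-corrected prefactor is
the default because micrometre-scale cell diameters then give the
single-digit µm³ volumes such measurements report. a > b is treated as a
labelling slip: axes are swapped with a warning. Per-condition summaries
use the sample (n−1) standard deviation.

## Synthetic-data generators

The generators emulate the study conditions and are the fixtures for every
test: defaults are an 8-point irradiance grid spanning 33–760 µmol photons
m⁻² s⁻¹, R_max = 0.20 h⁻¹, I_k = 164, no growth photoinhibition (β = ∞),
OD₇₃₀ setpoint 0.082 at 0.439 g AFDW L⁻¹ per OD unit (36 mg L⁻¹),
k_La = 0.83 min⁻¹, k_H = 1.08 mM atm⁻¹, O₂-free sparge, and 5 % measurement
noise — the relative spread reported for the measured rates. Noise is
multiplicative mean-one log-normal because rates are positive and their
reported scatter scales with the mean.

Simulated qO₂ is linked to growth through per-regime photosynthetic
quotients (Q_lim = 1.3, Q_sat = 0.6) via a continuous piecewise-linear
q_X → qO₂ map anchored at the I_k transition; this reproduces both regime
slopes and a maximal qO₂ near 9 mmol h⁻¹ g⁻¹ at μ = 0.20 h⁻¹
simultaneously. Dissolved O₂ is then the exact solution of the mass balance
for the realised (qO₂, D, x), so rate estimators can recover the generating
values to numerical precision (the zero-noise round-trip tests) and the
balance holds to 1e-12 by construction.

Expression matrices are built from four standardized piecewise-linear
archetypes over condition index — monotone up (saturating above the
transition), monotone down, minimum at the transition, maximum at the
transition — with arm slopes and breakpoints chosen so the four profiles
are linearly independent and no pair correlates above r ≈ 0.2 (negative
correlations are irrelevant to the eigengene-merge criterion). Genes are
archetype + N(0, sd) in standardized units, mapped to positive RPKM via
RPKM = scale·2^z so the analysis-side log₂/z-score transform recovers the
planted structure; default per-archetype gene counts are the published
cluster sizes (809/724/648/551). Annotation maps plant configurable
enriched categories inside chosen archetypes over a background of random
categories. With exactly 4 conditions four centered profiles cannot be
linearly independent (they live in a 3-dimensional subspace); ≥6 conditions
are needed for full rank, and the default is 8.

What the generators do **not** emulate: photon transport and self-shading,
pre-steady-state reactor dynamics, read-level sequencing noise
(RPKM-derived, not count-derived, noise), condition-correlated errors, and
fluorescence induction kinetics beyond piecewise-constant phase levels plus
the linear dark rise. Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
instrument systematics.

Ground truth travels in `truth_*` columns that the pipeline driver strips
before any estimator runs.

## Problem sizes and determinism

The test suite and the acceptance script run the Monte-Carlo checks at
explicit sizes chosen to make sampling error small relative to the asserted
tolerances: 200 replicate seeds for curve-fit and slope-recovery checks,
1,000 sampled 2×2 tables for the Fisher oracle, 800 genes (4 × 200) for
cluster recovery, and the full 2,732-gene configuration for the published
cluster-size percentages. All randomness flows through
`numpy.random.default_rng` seeded from explicit arguments; identical seeds
and configs give byte-identical outputs, and pipeline reports contain no
timestamps so reruns are directly diffable.

## Known limitations

- The O₂ balance is algebraic; transient DO excursions and carbonate
  chemistry are out of scope.
- The F-test model selection is a frequentist gate, not a model average;
  near-threshold inhibition may be reported as β = ∞ on noisy data.
- Enrichment P-values depend on the chosen universe; with an unknown
  original universe, ratios and P-values are reproducible only relative to
  the stated default.
- rETR is relative; absolute electron transport would require absorption
  cross-sections, which are not modelled.
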
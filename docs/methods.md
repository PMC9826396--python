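# Methods

`gravnet` implements an individual-based, gravity-model analysis of
functional connectivity: the degree to which a landscape permits effective
dispersal and gene flow among populations. It covers the full chain from
raster predictor surfaces and a spatial network to population-genetic
statistics and mixed-effects model competition, and ships a synthetic-data
generator with known ground truth so that every stage is testable without
any external download.

## The gravity model

For a directed edge from individual *i* to individual *j*, the response is
a gene-flow proxy and the model is, on the natural-log scale,

    ln(flow_ij) = β₀ + β_w ln(d_ij) + Σ_k β_k ln(v_jk) + Σ_l β_l ln(c_ijl) + u_i + ε_ij

* `v` — **at-site (production) covariates**: point values at the
  destination node (fine-scale surface relief `srr3`, annual dryness index
  `adi`, percent topsoil sand `sand`, percent shrub cover `shrub`, compound
  topographic index `cti`, heat load index `hli`). These proxy habitat
  productivity, the source of potential migrants.
* `c` — **between-site (resistance/facilitation) covariates**: medians of
  raster cells traversed by the straight edge (`srr27`, `imperv`, time
  since fire `fire`, `hli`, `cti`) plus the percent of traversed cells in
  the shrub land-cover class. Edges sample the landscape; they are not
  movement paths.
* `w` — geographic distance (planar Euclidean, meters), present in every
  model as the spatial-autocorrelation term.
* `u_i ~ N(0, σ_u²)` — random intercept per **origin site**. This is the
  singly-constrained realization: flows sharing an origin are not
  independent. (Destination grouping is available via the fitter's
  `group_col` argument.)
* `ε_ij ~ N(0, σ²)` — independent edge-level noise.

**Log-offset rule.** Every strictly positive column is logged directly.
A column containing zeros is logged as `ln(x + δ)` with `δ` = half its
smallest positive value. A column containing negatives is logged as
`ln(|x| + δ)` and the term is flagged: its effect direction is reversed in
the report. The generator and the fitter share one implementation of this
transform, which makes the generator exactly invertible: with zero noise a
refit reproduces the generating coefficients to machine precision.

**Estimation.** The random-intercept-only structure lets the fixed effects
and the residual variance be profiled out in closed form given the
variance ratio λ = σ_u²/σ²: block-diagonal V₀ = I + λZZ′ has an explicit
inverse per origin group. Fitting is a bounded one-dimensional search over
log λ (ML for model competition, REML for final estimates), deterministic,
with the λ → 0 boundary checked explicitly. A perfect fit (zero residual
variance, which has no likelihood maximum) falls back to least squares and
is flagged `degenerate`. The implementation is cross-checked against
statsmodels' MixedLM in the test suite; the profiled search typically lands
at an equal or slightly higher likelihood.

**Degrees of freedom (two-stratum rule).** Between-site covariates and
distance vary per edge and get residual df = n_edges − p (p = fixed
effects including intercept). At-site covariates repeat the destination
node's value over every incoming edge; they carry node-level information
only, so their t statistics use df = n_nodes − n_at − 2 (the additional 2
for the intercept and the distance term). An `"edge"` df rule (everything
edge-level) is available via `df_rule`.

**AIC and model competition.** AIC = 2k − 2·lnL with
k = fixed effects + 2 (random-intercept variance, residual variance), ML
fits only. The hierarchy runs in two rounds:

1. Round 1a competes each at-site ecological process model (fine-scale
   topography, microclimate, soil, vegetation = {shrub, cti},
   thermoregulation = {hli}) against an at-site global model and the
   distance-only null; round 1b does the same for the between-site
   processes (vegetation, thermoregulation, development, fire, broad-scale
   topography). Non-null models with ΔAIC < 4 of the round best advance.
2. Round 2 competes the union of every surviving at-site model with every
   surviving between-site model (a side with no partner competes alone),
   plus the global–global model and the null. Duplicate covariate sets
   collapse to one entry; ties in rank break lexicographically by name.

The **selected** model is the most parsimonious model within ΔAIC < 4 of
the round-2 best. This is deliberate: under a support threshold of 4,
models inside the window are statistically equivalent, and choosing the
smallest one prevents spuriously enriched models from displacing a simpler
truth. With strong effects on all covariates the global–global model wins
outright; with distance-only data the null is selected unless some
covariate union clears the full 4-unit penalty by chance (see
*Limitations*).

**Effect sizes.** Under the REML refit of the selected model, each term's
Cohen's D = 2t/√df. The default confidence interval is the
large-sample one, D ± z·se with se = √(4/df + D²/(2df)); a fixed-width
variant (±1.40·2/√df) is available via `ci_rule="calibrated"`. A term is a
driver when its CI excludes zero. The reported direction is sign(D) with
two reversals compounded: one when the covariate is negative after the
log transform (typical raw value below 1, e.g. ratios in [0, 1]; for
raw-negative columns this compounds with the magnitude flip), and one for
between-site terms (the resistance orientation of the gravity equation,
mirroring how the source tooling parameterizes the `c` term). The
interpretation report compares this direction with each covariate's
registered ecological prediction (supported / contradicted /
insignificant). On synthetic data the generator encodes effect signs on
the flow directly, so between-site verdicts follow this reporting
convention rather than the generator's coefficient signs.

## Population-genetic statistics

* **Genetic distance**: Euclidean distance between diploid dosage vectors
  over pairwise-complete loci, rescaled by √(L/L_complete) so missingness
  does not shrink distances. **Gene flow** = 1 − d/max(d) ∈ [0, 1].
* **AMOVA**: locus-by-locus nested analysis of variance on alleles with
  three strata — within individual, among individuals within populations,
  among populations — using unequal-size coefficients (n_c) and summing
  variance components over loci before forming F_IT, F_IS, F_ST
  (ratio of sums). The identity (1−F_IT) = (1−F_IS)(1−F_ST) then holds to
  machine precision. Negative components are retained in the F statistics
  and floored at zero for the percentage table (both are reported).
  Missing genotypes are handled listwise per locus.
* **F′_ST**: F_ST divided by its maximum attainable value, recomputed
  after recoding each population's alleles as population-private
  (indicator allele distance); F′ = 1 when populations share no alleles.
* **Pairwise F_ST**: the two-population AMOVA θ (may be slightly
  negative; not clamped). A Weir–Cockerham per-locus variant is provided
  for cross-checks and agrees closely on simulated data.
* **Permutation tests**: individuals permuted among populations (F_ST) or
  alleles re-paired within populations (F_IS);
  p = (1 + #{perm ≥ obs}) / (n_perm + 1). One seed drives counter-based
  child streams (`SeedSequence(seed, spawn_key)`), so tests are
  reproducible and independent of evaluation order. Default 9999
  permutations.

## Terrain predictor surfaces

* **Surface relief ratio** (windows 3×3 and 27×27 cells on a 30 m DEM):
  (mean − min)/(max − min), nodata excluded from window statistics, flat
  windows defined as 0.5 (the linear-ramp limit). The cell-window reading
  is used because a 3 m window is unrepresentable at 30 m resolution.
* **Slope/aspect**: Horn 3×3 operator; aspect at zero slope set to the
  225° fold axis so the heat load there equals its slope-zero closed form.
* **CTI** = ln(A_s/tan β): D8 single-flow-direction accumulation
  (steepest descent; ties broken in fixed E,SE,S,SW,W,NW,N,NE order),
  A_s = accumulated cells × cell size, tan β floored at 10⁻⁴. No pit
  filling or multi-flow routing.
* **HLI**: the published exponential in latitude, slope and folded aspect
  (fold about the SW axis), strictly positive.
* **ADI** = dd5/MAP: dd5 sums max(0, T̄_month − 5 °C) × days-in-month over
  a non-leap calendar (simple clamp-sum, not a sine interpolation);
  non-positive precipitation becomes nodata.
* **Resampling**: nearest or bilinear onto the same extent; categorical
  grids (land cover, fire year) are restricted to nearest.

## Network construction and edge sampling

Directed edges connect every ordered pair of individuals within the
pruning distance (10 km default, 50 km alternative); lengths are planar
Euclidean meters. Cells under an edge are collected by a **supercover
traversal**: the segment is sliced at every grid-line crossing and each
sub-segment midpoint indexes one cell, so every cell whose interior the
open segment crosses is counted exactly once (verified in tests against an
exact Liang–Barsky clipping oracle and a dense-sampling oracle). Cell
membership uses the half-open convention (boundary points belong to the
higher-index cell). Statistics: mean, median (the exported default), min,
max, variance, skewness, kurtosis, and nearest-rank (type-1) q75/q90/q95.
Buffered sampling collects cells whose centers lie within a half-width of
the segment; `buffer_sensitivity` reports Pearson r of per-edge summaries
between widths (30/90/250/500 m). A correlation screen flags covariate
pairs with |r| ≥ 0.70 and retains the member registered in more ecological
hypotheses.

## Synthetic-data generator

The generator's defaults emulate the study scale: 9 sites × 15
individuals (135 ≈ the study's 134), 30 m grids, thousands of biallelic
SNPs, and a 10 km pruned network.

* **Landscape**: each surface is Gaussian-kernel-smoothed white noise
  (kernel length 5 cells) — DEM (amplitude 300 m), a 12-band monthly
  temperature stack (coastal-Mediterranean seasonal cycle 12–22 °C plus a
  spatial field), annual precipitation (~400 ± 150 mm), percent sand —
  plus disk-patch urban imperviousness (target 15% of cells above 50%,
  with the realized fraction book-kept for tests), patch-structured fire
  years over an unburned sentinel, and a land-cover grid dominated by a
  shrub class with grass/forest/developed classes. Surfaces are drawn from
  independent child streams of one seed, so runs are bit-reproducible and
  stages are independent.
* **Individuals**: site centroids on a jittered lattice with a 15% margin;
  Gaussian scatter 120 m around the centroid (tight clusters relative to
  ~1 km site spacing, mirroring clustered field sampling), with bounded
  redraws at the grid boundary.
* **Genotypes**: Balding–Nichols island model. Ancestral frequency
  p ~ U(0.05, 0.95); site frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with a
  scalar or per-site divergence target F (default 0.2, near the study's
  observed mean differentiation); diploid dosages Binomial(2, p_site);
  uniform missingness (default 5%). Expected pairwise F_ST between sites
  with targets F_a, F_b is (F_a+F_b)/2, giving closed-form calibration
  targets; a per-site span of targets reproduces the study's wide
  differentiation range.
* **Flows**: generated directly from the gravity equation above (default
  β: −0.5 on distance, ±0.3 on covariates following the registered
  ecological predictions; σ_u = 0.1, σ_ε = 0.1), with the generating u and
  ε stored for recovery tests. Flows are drawn on the equation, not from a
  forward genetic simulation: this validates the inference machinery, not
  coalescent realism, so passing tests demonstrate correct estimation
  given the model, and say nothing about model adequacy for real
  landscapes (no isolation-by-environment genetics, no drift, no temporal
  dynamics).

## Problem sizes used in the automated checks

Chosen to keep the full suite to a few minutes on one core: coefficient
recovery runs 50 replicates of the default study (≈18 000 directed edges
each); model-selection behaviour runs 20 replicates per scenario; F_ST
calibration uses 2 000 loci × 30 individuals per population; the
permutation-uniformity check uses 200 panmictic replicates × 99
permutations × 300 loci (the p-value lattice at 1/100 is far finer than
the KS critical deviation at n = 200); AMOVA permutation defaults stay at
9999 for real analyses but small counts in tests.

## Known limitations

* With ~12 independent candidate covariates, distance-only data still
  yields a spurious round-2 union beating the null by more than 4 AIC
  units in roughly 10–15% of replicates — an inherent multiple-comparison
  property of AIC competition, not an estimator defect (the spurious t
  statistics are calibrated to sd ≈ 1.0). Expect null recovery in ~85–90%
  of replicates, not 100%.
* At-site covariates vary essentially at the site level (~9 effective
  observations under the default geometry); with the variance ratio
  estimated from 9 origin clusters their Wald CIs are mildly
  anticonservative (empirical z-sd up to ~1.2). A Kenward–Roger-style
  small-sample correction is not implemented.
* CTI uses uncorrected D8 on the raw DEM; internally drained cells keep
  their accumulation (no pit filling).
* Geographic distance is straight-line planar; topographically corrected
  (surface) distance and least-cost/circuit alternatives are out of scope.
* The gene-flow response is scaled by the observed maximum distance, so it
  is relative within a dataset, not comparable across datasets.
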
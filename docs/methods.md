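# Methods

This note records the models, numerical choices and design decisions
behind each stage, and what the synthetic tests do and do not demonstrate
about field data.

## Chemotaxonomic model

The pigment table S (samples × pigments, ng/L, ten diagnostic pigments
plus total chlorophyll *a*) is modelled as S ≈ C·F with C ≥ 0 the samples ×
groups chlorophyll-*a* contributions and F the groups × pigments ratio
matrix whose chlorophyll-*a* column is fixed at 1. The five default groups
are Bacillariophyta, Chlorophyta, Cryptophyta, Cyanophyta and Pyrrophyta;
a sixth microscopy group (Euglenophyta) is accepted by the counting module
but excluded from the pigment comparison.

**Optimizer.** The classic implementations of this factorization use
steepest descent; here estimation is a deterministic alternating scheme in
which both half-steps are exact:

* *composition step* — per-sample non-negative least squares
  (`scipy.optimize.nnls`) on the weighted pigment columns;
* *ratio step* — bounded minimisation over one pigment column of F by
  exact coordinate descent (each coordinate update is the unconstrained
  minimiser clipped to its box).

Each iteration begins with a fresh composition solve. The first
iterations (as many as there are free columns) update only the single
column whose re-fit most reduces the residual; afterwards all columns are
updated in one block sweep per iteration. The greedy phase matters when
the starting matrix is wrong in only a few entries: updating every column
against one stale composition can wander along near-degenerate directions
of the factorization in which several (C, F) pairs fit equally well,
whereas re-solving compositions between single-column updates keeps the
path anchored to the nearest coordinate-wise optimum. The block phase
then converges quickly when the fit is broadly wrong. Because every
half-step is an exact minimisation of the same objective, the weighted
RMSE never increases.

**Bounds.** Free entries stay within ±`ratio_limit` (default 50%) of
their value at the start of the run and ≥ 0; entries that start at zero
stay zero (they encode "this group lacks this pigment"). The
chlorophyll-*a* column is never updated. `successive_runs` chains ten
bounded runs, re-centring the bounds on each run's output — ratios can
drift far from the literature starting point over the chain while each
individual run stays controlled, and the RMSE after each run is recorded.

**Weighting.** Pigment columns are weighted by the inverse of their
column maximum in the initial ratio matrix (identity weighting
available). Unweighted fits are dominated by total chlorophyll *a*, which
is one to two orders of magnitude larger than any accessory pigment.

**Convergence and degeneracies.** Iteration stops when the relative RMSE
improvement falls below 1e−6 or after 500 iterations; non-convergence
returns the best-so-far matrix with a warning flag, never an exception.
All-zero samples get zero composition and a flag. In rank-deficient fits
the active-set NNLS solution (a vertex of the feasible set) is returned.
Note that when two ratio rows share a pigment, the factorization can be
non-identifiable within the bounds even on noiseless data (a bounded
family of exact fits exists); with the default matrix the pinned zero
pattern blocks these directions. Ten re-centred runs on noisy data let
ratios adapt to noise, which can erode the marker correlation of minor
groups — the marker validation table makes this visible.

## Microscopy

Abundance follows the settle-and-count formula
N = (A/Ac)·(V1/V0)·(n/V)·1000 cells/L with defaults A = 400 mm²,
V = 0.1 mL, V0 = 500 mL, V1 = 30 mL. Triplicate counts are averaged
(sd reported; NaN for a single replicate). The method comparison is an
ordinary least-squares fit of log10 concentration on log10 abundance,
pooled over all samples, because both quantities span orders of
magnitude; zeros cannot enter a log fit and are excluded with their count
reported, and groups with fewer than three positive pairs are skipped.

## Realized niches

For each group × variable the chain is GAM → maximum-entropy
normalisation → moments:

1. **Response curve.** A penalized cubic B-spline smooth of
   log(c + ε) on x, basis dimension 6 (clamped cubic B-splines, interior
   knots at quantiles), second-order difference penalty on the
   coefficients, penalty weight chosen by minimising
   GCV(λ) = n·RSS/(n − edf)² over a 41-point log-spaced grid
   (λ ∈ [1e−4, 1e6]). With six basis functions each candidate is a 6 × 6
   solve, so the grid search is exact and cheap. ε defaults to half the
   smallest positive concentration of that group — zeros stay finite
   without dominating the log scale. Fewer observations than the basis
   needs reduce the basis with a warning; constant x is an error.
2. **Occupancy density.** p(x) = exp(f(x))/∫exp(f(u))du — the
   least-informative (maximum-entropy) density consistent with the fitted
   log-response — evaluated by trapezoidal quadrature on a 256-point
   linear grid over the *observed* range of x (realized, not fundamental,
   niche). The grid spans the 0.5–99.5% quantiles of x rather than the
   strict min/max: beyond the extreme half-percentiles the smooth is
   supported by a handful of points, and exponentiation would let edge
   wiggles of the spline dominate the density. max f is subtracted before
   exponentiating to prevent overflow.
3. **Moments.** μ = ∫x·p dx and σ = (∫(x−μ)²·p dx)^{1/2} by trapezoidal
   quadrature on the same grid.
4. **Bootstrap.** Percentile intervals (not BCa) at the 95% level from
   100 case resamples of the (x, c) pairs, mirroring the standard
   reporting convention for these niche parameters. Each replicate
   repeats the full chain on its own observed range; replicates that fail
   (e.g. a degenerate resample) are dropped and counted, and more than
   20% failures flags the estimate unstable. The point estimate always
   comes from the full data and is independent of the seed.

All samples (all depths and cruises) are pooled per estimate. Samples
with missing values of a variable are dropped for that variable only;
requested variables absent from the environment table are reported and
skipped, not fatal.

## Ordination

**CCA** uses the weighted-averaging eigen formulation: with P = Y/total,
row masses r and column masses c, the chi-square standardized residual
matrix Q̄ = (P − rcᵀ)/√(rcᵀ) is projected onto the span of the row-mass
weighted, weighted-centred constraints, and the projection is decomposed
by SVD. Canonical eigenvalues are the squared singular values; the
proportion explained is their sum over the total inertia ‖Q̄‖². The
implementation agrees with an independent generalized-eigenproblem
solution and with R vegan's `cca` to printed precision (both checked in
the tests). Collinear constraint columns are detected by the QR diagonal
and dropped with their names reported; all-zero sites or species are
dropped with a notice. Species scores use species-focused (scaling-2)
weighting; biplot arrows are weighted correlations of the variables with
the constrained site axes. The community matrix enters untransformed
(concentrations in ng/L); a log1p option is available on the pipeline
level by transforming beforehand.

**Trait PCA** pivots the niche table to one row per group with μ and σ
per variable, z-scores each trait (sample sd), and decomposes the
correlation matrix via SVD of the standardized matrix. Constant traits
are dropped with a warning; groups with missing traits are removed
listwise. Variance fractions are eigenvalues over their sum.

**Clustering** is Ward hierarchical agglomeration on Euclidean distances
of the *standardized* PC1–PC2 scores. The scree curve is the
within-cluster sum of squares at every cut of the tree; for k = "auto"
the cluster count maximises the second difference of that curve (the
elbow). If all points coincide the answer is one cluster. The elbow rule
is geometry-dependent — for strongly elongated arrangements it can prefer
k = 2 — which is the usual caveat of scree-based selection.

## Synthetic reservoir generator

The generator emulates a warm monomictic drinking-water reservoir
surveyed on repeated cruises: 12 stations with surface samples, four key
stations profiled at 0/5/10/20/30 m, seven cruises covering all four
seasons (December–February winter, and so on). Each environmental
variable follows mean + amplitude·season + gradient·depth·stratification
+ Gaussian noise, where the seasonal factor is +1 in summer and −1 in
winter and the vertical gradient acts only while the column is stratified
(fully in summer, weakly in spring). Non-detects are censored at the
configured detection limits (e.g. DRP 0.019 μmol/L) and stored as half
the limit with a flag.

Group biomass is a separable Gaussian niche,
B(g,i) = K_g·∏_v exp(−(x_iv − μ*_gv)²/2σ*²_gv), times mean-preserving
multiplicative lognormal noise (CV 0.3 by default) — lognormal keeps
concentrations positive and matches the right skew of field biomass.
Pigments are B·F* with the known ratio matrix plus the same lognormal
noise model; counts are Poisson with mean equal to the expected cells in
the counted aliquot, in triplicate.

**Identifiability by design.** The defaults are chosen so that the
univariate niche estimator's assumptions hold: temperature alone carries
the seasonal cycle and the thermocline, while the other niche axes vary
mostly independently (weak seasonal amplitude, no vertical gradient) —
strongly collinear gradients would confound *any* marginal method, since
the realized niche along one variable then genuinely differs from the
generating optimum. Niche optima sit within ~0.6 sd of each variable's
centre and breadths are comparable to the variable's spread; an optimum
near the edge of the sampled range, or a breadth far wider than it, is
not recoverable from occupancy data in principle. The niche pattern
encodes the qualitative guild structure of such reservoirs: a warm,
alkaline, nutrient-associated pair (Chlorophyta, Cyanophyta with optima
≈ 26.6/27.0 °C), a cool silicate-associated pair (Bacillariophyta,
Cryptophyta ≈ 21.5/21.8 °C), and dinoflagellates set apart by low pH/DO
optima and the widest pH and phosphorus tolerances.

**What passing tests show — and do not.** Parameter recovery on this
generator demonstrates that the pipeline is implemented correctly and is
statistically consistent under its own assumptions. Field data violate
those assumptions in known ways: environmental covariates are mutually
correlated (so realized niches along single variables absorb
confounding), niches need not be Gaussian or separable across variables,
pigment ratios vary with light and nutrient history within a survey, and
counting error is over-dispersed relative to Poisson. Recovery on the
synthetic survey therefore validates the machinery, not the ecological
identifiability of any particular field dataset.

**Problem sizes.** The default survey has 196 samples (12 stations ×
7 cruises + 4 profile stations × 4 extra depths × 7 cruises). Parameter-
recovery checks extend the calendar to 18 cruises (504 samples) — the
size at which the recovery tolerances are stated — and the bootstrap
coverage simulation uses 200 Monte-Carlo repetitions of n = 300 samples
with a 64-point density grid, whose Monte-Carlo error on a ~94% coverage
is about ±1.7 percentage points. The coverage simulation samples the
variable symmetrically around the true optimum so that the
range-truncated realized niche mean coincides with the generating μ*;
with an asymmetric window the estimand itself shifts by the truncation
and coverage of μ* is no longer the right question.

## Pipeline

`run_pipeline` chains chemotaxonomy → microscopy comparison → niche
estimation → ordination, writes each stage's tables, and emits
`report.json` with: TChl *a* range, per-season group percentages of
TChl *a*, the per-sample NOx/DRP molar-ratio summary (phosphorus-
deficiency indicator), the niche table, CCA proportion explained, PCA
variance fractions and the cluster assignment. Input validation checks
schemas, non-negativity and sample-id alignment; misaligned ids are
fatal with the offending ids listed, a missing requested variable is a
warning and the variable is skipped. Units are fixed by the schema
(ng/L, μmol/L, °C); no automatic conversion. Seasons derive from dates
by the December–February = winter convention. A YAML file configures the
pipeline; CLI flags override config keys. Stage failures are recorded in
the report and produce a non-zero exit code.

## Known limitations

* The successive-runs protocol can overfit pigment noise through ratio
  drift; inspect the marker-correlation table and the RMSE trajectory.
* Niche estimates are univariate marginals; with correlated environments
  they describe realized occupancy, not causal response.
* Breadths wider than the sampled range are reported as truncated
  (range-limited) breadths.
* The CCA omits permutation significance tests, and cluster-count
  selection by scree elbow is heuristic.
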
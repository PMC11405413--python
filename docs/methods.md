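# Methods

This note documents the statistical model behind `ctcoloc`, the choices
made where the design was genuinely open, what the synthetic generators
emulate, and the known limitations.

## Data model

All spatial analyses operate on *parcel maps*: one scalar per cortical
parcel with parcel identity carried by label strings (a bundled
148-label Destrieux registry can validate real inputs).  Cross-map
operations require identical parcel order and refuse to reindex
silently.  Z-standardization across parcels uses the population SD
(denominator n); the maps are descriptive, and the convention cancels in
rank correlations and R².  Missing values are rejected rather than
imputed.

## Relative CT change and windows

Relative modeled CT change between ages i and j is
ΔCT(i,j) = (CT_j − CT_i)/CT_i per parcel, computed on the median
(50th-percentile) sex-average slice of the normative CT table, where
"sex-average" means the mean of the female and male CT grids *before*
the change computation.  The lifespan scan uses windows (i, i+5) for
i = 5…85 in 1-year steps (81 windows); a broad (5, 30) window is
appended for developmental analyses (82).  Window endpoints must lie on
the 0.5-year age grid — there is no interpolation, because the normative
model is exported on a fixed grid.  Window labels for reporting use the
midpoint (Δ(5,10) → 7.5); internal arithmetic always uses endpoints.
A sensitivity flag residualizes ΔCT on baseline CT across parcels
(linear, with intercept); alternative window lengths are plain
parameters of the window builder.

## Surrogate-map null model

Across-parcel correlations cannot be tested parametrically: the number
of parcels is an arbitrary resolution choice and neighboring parcels are
strongly dependent.  Every inferential statistic is therefore compared
to the same statistic computed with *surrogate* predictor maps that
preserve the predictor's spatial autocorrelation:

1. randomly permute the map's values (destroys structure, keeps values);
2. smooth the permutation with exponential distance-decay kernels
   truncated at k nearest neighbors, for a ladder of ~8 scales spanning
   5–50% of the parcels;
3. for each scale, fit the source map's variogram with a nonnegative
   affine combination of the smoothed field's variogram and a white-noise
   term (closed-form least squares), and keep the best-fitting scale;
4. rank-remap the winning candidate onto the source value multiset
   (so every surrogate holds exactly the original values — mean, SD and
   all quantiles are preserved by construction).

Variogram fitting and the fidelity metric use a Gaussian-kernel-smoothed
semivariance curve evaluated at 25 points over parcel pairs within the
25th percentile of pairwise distances.  The truncation matters: spatial
autocorrelation lives at short range, while the long-range
(interhemispheric) part of the variogram is a noisy, uninformative sill;
fitting it degrades the surrogates, and even two independent draws of
the same process disagree in its bin ranks.  A plain equal-count binned
variogram (`empirical_variogram`) is kept as the descriptive estimator.
One distance matrix covers all 148 parcels (Euclidean centroid
distances); interhemispheric distances are large, so the kernels act
effectively within hemisphere.

Surrogate ensembles are generated once per predictor map, cached keyed
by (map, seed, parameters), and reused across all windows; the default
ensemble size is 10,000 (tests and examples use 1000).

Empirical p-values use the valid finite-sample estimator
p = (1 + #{null ≥ observed})/(1 + N), one-sided, ties counting against
the observation; the minimum is 1/(N+1) and p is never 0.  FDR control
is Benjamini–Hochberg within declared families: combined-model scans
form one family across modalities, univariate scans are corrected within
modality, dominance scans in one family across all windows and
predictors (e.g. 82 + 82×9 tests), and the gene-trajectory tests in one
family over all marker × statistic pairs.

*Calibration.* Conditional on a single atlas realization, surrogate R²
distributions can be slightly offset from the truth (the p-values for
one fixed atlas are mutually dependent); averaged over atlas
realizations the procedure is calibrated.  The acceptance check
therefore pools 25 independent atlases × 20 independent GP outcome maps
(500 replicates at 1000 surrogates): the pooled p-values are uniform
(KS) and the type-I rate at α = 0.05 falls within [0.03, 0.07].

## Scans and dominance analysis

Univariate: OLS of the change map on one z-scored predictor
(R² identical to the squared Pearson correlation); the Spearman rho is
reported for the association sign.  Multivariate: OLS on all predictors
of a modality with intercept; adjusted R² reported as computed (it may
be negative).  Null distributions replace the predictors *jointly* —
one fresh surrogate per predictor per iteration — rather than permuting
the outcome, which preserves each predictor's autocorrelation under the
null.  Predictors are z-scored, change maps stay in native relative
units.

Total dominance of predictor x is the average over subset sizes k of the
mean incremental R² gained by adding x to each size-k subset not
containing x, enumerated exactly over all 2^p subsets (hard cap p = 15;
the intended scale is ~9 predictors).  Plain (not adjusted) R² is used
inside the decomposition because only plain R² makes the contributions
sum exactly to the full-model R² (verified to 1e-10); adjusted R² is
reported for the full model only.  Subset R² values are computed from
predictor/outcome correlation matrices (R²(S) = c_Sᵀ C_SS⁻¹ c_S),
batched over subsets and outcomes, which makes the 82-window × 1000-null
scan run in seconds.  An independent brute-force oracle (average
incremental R² over all p! predictor orderings) is used in tests; the
two formulations agree to numerical precision.

Regional influence: ΔPE = |residual of the model without x| − |residual
of the full model| per parcel; positive where x improves the fit.  The
residual-difference formula (dropping a predictor, not a region) is the
implemented definition.

## Factor reduction

Extraction is minimum-residual (ULS) on the atlas correlation matrix:
uniquenesses are optimized (L-BFGS-B, analytic gradient, bounds
[0.005, 1], tolerance 1e-6) so that the discarded eigenvalues of
R − diag(ψ) are minimal; loadings come from the leading eigenpairs of
the reduced matrix.  Retention: k grows while every unrotated factor's
SS-loading proportion of total variable variance (denominator = number
of maps) stays ≥ 1%, up to the Ledermann bound.  Rotation is promax
(power 4) via the varimax-based target procedure; factor correlations
Φ = TᵀT, structure = pattern·Φ; each factor is oriented so its
top-loading atlas loads positively.  Scores are Thurstone regression
scores, z-scored per factor.  Rotated variance per factor is the SS of
structure loadings over the number of maps; its cumulative sum can
exceed the unrotated total because oblique factors overlap — it is
reported with that caveat.  Single-map modalities pass through unreduced
(the microstructural `mr1` convention).  Validation refits the entire
retention+rotation pipeline on libraries whose parcel order is permuted
independently within each map and compares cumulative rotated variance
(one-sided empirical p).

Two properties of the retention rule are worth knowing.  First, it
counts *common* variance: a library of exactly uncorrelated maps has no
common factors and the fit raises an advisory error instead of retaining
p trivial factors (a PCA-style rule would behave differently).  Second,
on sampled data — especially spatially autocorrelated maps, whose
effective sample size is far below the parcel count — the 1% threshold
is liberal enough to pick up borderline sampling factors, so the
retained count on noisy realizations of a k-factor model is k or
slightly more.  Recovery tests therefore use the generator's
`exact_structure` option, which orthogonalizes latents and noise so the
sample correlation matrix satisfies the k-factor model exactly; on such
data the rule returns exactly k with loading congruence ~1.

## Gene-expression trajectory validation

For a marker with gene set G and significant period P: average the
(normalized, log2) expression across G per subject, fit LOESS over
postnatal age (locally quadratic, tricube weights, span 0.75, evaluated
on a 0.5-year grid inside the observed age range, no extrapolation;
minimum 8 subjects), and compute the curve's mean inside P, outside P,
and their ratio.  The null references are n_null same-sized gene sets
drawn from a pool of genes not detected in brain, pushed through the
identical pipeline; p is positive-sided with the (k+1)/(N+1) convention,
and one null ensemble per set size serves all markers of that size
(mirroring a constant null dataset).  For fixed subject ages LOESS is
linear in the expression values, so the smoother is exposed as a matrix
and the full 10,000-draw resampling costs one matrix product.  The mean
statistic is invariant to adding a constant to all genes; the ratio is
not — both behaviors are asserted in tests.

## Cohort transfer

Per-subject relative change uses the same ΔCT formula on observed
two-session CT; subjects missing a session are excluded with a logged
count.  Both the change of the cohort-mean CT and the mean of subject
change maps are available (they differ slightly because the change is a
ratio).  Per-subject dominance is the identical exact decomposition.
The group-level test compares the across-subject mean full-model R² (and
each mean total dominance) to n_null = 1000 null analyses in which the
whole predictor set is replaced by one jointly drawn surrogate set,
reused across subjects within an iteration — the statistic under test is
the group mean, so the exchangeability argument stays on the atlases.
Site and sex covariate adjustment and harmonization are out of scope;
the cohort generator emits already-harmonized data and externally
harmonized tables are accepted as-is.

## Synthetic generators

The generators emulate the *structure* of the real inputs, not their
content:

- **Geometry**: jittered Fibonacci lattices on two spherical caps
  (radius 40, centers ±50 in x) stand in for the hemispheres; Euclidean
  centroid distances replace geodesics.
- **Marker maps**: zero-mean GP draws with exponential covariance
  exp(−d/ℓ), ℓ = 25 by default (about 30% of the within-hemisphere
  extent), z-scored; cross-map correlation r is induced by a shared GP
  component (feasible for 0 ≤ r < 1).  The kernel family matches the
  variogram family the surrogate method assumes, which keeps the
  calibration experiments interpretable.
- **CT trajectories**: CT(p,a) = B(p)·g(a)^(1+δD(p))·(1+m·M(p)·ramp(a))
  with a positive GP baseline B (~2.5 mm), a smooth declining age factor
  g, an optional small GP "aging-rate" drift D (δ = 0.05 in the study
  scenario; 0 by default so that a silent mixture yields exactly uniform
  change), and a smoothstep ramp over the target window carrying the
  designed mixture M = Σw_k·atlas_k + noise at 3% modulation.  The noise
  is a GP draw orthogonalized against the atlas columns, so the realized
  OLS R² of the target-window change on the true atlases equals the
  requested construction R² exactly; percentile and sex structure is
  multiplicative and cancels in relative change.  Default grid 5–90
  years in 0.5-year steps (171 points), 7 percentiles, 2 sexes.
- **Expression**: 33 subjects by default, log-spaced ages 0.33–82.05
  years; genes are baseline + iid noise (within-gene SD 0.5 log2 units),
  signal genes add a raised-cosine bump of 2 within-gene SDs inside the
  peak period; 2154-gene non-brain pool; markers are 5-gene sets.
- **Cohort**: 100 subjects / 20 sites by default, two sessions;
  CT = population trajectory at the session age + subject GP intercept
  map + site GP offset map + iid noise, i.e. already harmonized.

What passing on these data does *not* show: robustness to non-GP
autocorrelation (real cortical maps have anisotropic, network-like
structure), geodesic-versus-Euclidean distance effects, scanner/site
scale interactions, realistic normative-model uncertainty, or any claim
about the real deposited atlas data.

## Problem sizes and numerics

The test suite and the acceptance protocol run at the study's structural
scale (148 parcels, 9 predictors, 82 windows, 33 expression subjects,
2154-gene pool) with 99–1000 surrogates per ensemble where ensembles are
needed; calibration experiments use 500 replicates (25 atlases × 20
outcomes), parameter recovery 50 replicates, cohort examples 8–30
subjects.  Numerical guardrails: GP covariances get a 1e-8 diagonal
jitter; correlation matrices with condition number > 1e10 raise
conditioning errors (duplicate maps, rank-deficient designs); constant
maps are rejected wherever a correlation or surrogate is requested;
dominance identity is enforced at 1e-10; z-scored maps satisfy the
mean-0/SD-1 invariant at 1e-9.  All generators and analyses are
deterministic given their seeds, and the pipeline manifest records every
seed and parameter needed to reproduce a run.

## Known limitations

- Surrogate quality is assessed against the smoothed short-range
  variogram; maps whose structure is dominated by long-range or
  interhemispheric patterns are outside the method's design envelope.
- Conditional on one predictor map, surrogate-based p-values carry a
  small realization-specific bias (see Calibration above); single-map
  borderline p-values near α should be read accordingly.
- The factor retention count on noisy data is a liberal estimate by
  design; it is exact only when the factor model holds in-sample.
- The dominance cap (p = 15) is a hard enumeration limit; approximate
  decompositions for larger predictor sets are deliberately not
  provided.
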
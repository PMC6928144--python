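# Methods

## Slice-weighted lesion load

All volumes are binary 3D masks on one shared voxel grid; registration is
out of scope and `check_same_grid` enforces the precondition (shape
equality, affines agreeing elementwise to 1e-4 absolute — enough to absorb
float serialization noise, tight enough to reject genuinely different
grids). On read, volumes are reoriented to the closest-to-RAS canonical
orientation so the third array axis is the axial (z) direction; the
weighting is defined per axial slice, so this convention makes the
per-slice quantities well defined. Any strictly positive voxel value is
binarized to 1 with a logged warning — probabilistic inputs lose
information under this collapse and the log surfaces it.

For tract X with slice areas `m(x)` and maximum slice area `m(x*)`, and a
lesion contributing `n(x)` voxels inside the tract on slice `x`:

    w-X-LL = Σ_x n(x) · m(x*) / m(x)

summed over slices where the tract is present (`n(x)` lives on the tract's
own support, so no division by zero can arise). The result is a
dimensionless "weighted voxel" count: equal to the raw overlap for a
constant-area tube, strictly larger whenever damage falls on slices thinner
than the widest one. A millilitre conversion (× voxel volume) is available
but the analysis operates in weighted voxels, there being no canonical unit
for the weighted quantity.

Two hemisphere policies are provided and logged: `ipsilesional` (default)
scores each subject against the template of the affected hemisphere
recorded in the cohort table; `flip-to-canonical` mirrors lesions about the
grid's midsagittal plane onto a single template side. Both appear in the
lesion-load literature; the choice is explicit config, never implicit.
The whole-CST predictor (`w-SMATT-LL`) uses the union mask's own slice
profile, not the sum of sub-tract loads: the union is a tract like any
other, and profiling it directly keeps the formula uniform. The alternative
(summing sub-tract loads) double-counts voxels shared by overlapping
sub-pathways.

## Association statistics

Spearman ρ uses mid-rank ties with the two-tailed p-value from the
t-approximation `t = ρ√((n−2)/(1−ρ²))` on n−2 df — the behaviour of
mainstream statistics packages at cohort sizes around n = 27; an exact
permutation option exists for n ≤ 10. Correlation magnitudes are labelled
by the Munro bands 0.00–0.25 little/none, 0.26–0.49 low, 0.50–0.69
moderate, 0.70–0.89 high, 0.90–1.00 very high (band lookup on |ρ| rounded
to two decimals; edges are config-overridable). Missing data are handled by
pairwise-complete deletion with dropped counts logged; a constant vector
makes the correlation undefined — the matrix records NaN with a warning
rather than failing the run, since a small cohort can leave a medial tract
untouched.

## Dominance analysis

All 2^p subset regressions are fitted exhaustively (p = 7 → 128 models;
centred least squares, one solve per subset). Additional contributions
ΔR²(x|S) = R²(S∪{x}) − R²(S) are clipped at zero within a 1e-10
floating-point guard. Dominance uses the strict-inequality convention:
complete dominance requires ΔR²(x|S) > ΔR²(y|S) for *every* subset S of the
remaining predictors; conditional compares the size-k averages at every k;
general compares the grand averages (whose sum over predictors equals the
full-model R² — an identity the tests assert to 1e-9). Ties leave the
relation undetermined; no direction is ever awarded on a tie. Complete ⇒
conditional ⇒ general holds by construction and is property-tested against
exhaustive enumeration.

Reproducibility: B case resamples (with replacement, seeded) rerun the
whole analysis; the reproducibility of a pairwise designation at a level is
the fraction of resamples whose designation matches the original sample's.
Resamples with a constant predictor are redrawn (at most 100 times, then
counted as non-reproducing and logged). A predictor's "reproducibility
range" is the min–max of its pairwise general-dominance values. Rank
deficiency inside a subset model falls back to the minimum-norm solution
and is flagged, not hidden.

## Prediction model

Stepwise OLS on probability-of-F: at each iteration the best remaining
candidate enters if its partial-F p-value ≤ 0.05, then any included
predictor with removal p ≥ 0.10 leaves; the 0.05/0.10 pair is the
ubiquitous default of commercial statistics software and is
config-overridable. `p_enter < p_remove` is enforced to preclude cycling.
Each model change is a recorded step with R, R², adjusted R², R²-change
(partial-F p) and SEE. Age enters dichotomized at ≥ 70 years (the cut is
config).

Diagnostics follow the conventional battery: pairwise predictor
correlations flagged at |r| ≥ 0.9; outliers flagged at |standardized
residual| > 3; homoscedasticity delivered as (standardized predicted,
studentized residual) plot pairs — deliberately no numeric test is
substituted for what is a visual check; Kolmogorov–Smirnov of standardized
residuals against a standard normal (a Lilliefors-corrected variant is an
option, since the standardization estimates parameters); Durbin–Watson d
over the supplied case order — the data are cross-sectional, so d is
order-dependent; the order used is recorded in the report rather than the
ambiguity being hidden. Coefficient CIs come from a percentile
case-resampling bootstrap (default B = 1000, 2.5/97.5 percentiles, seeded,
same degenerate-resample redraw policy). Adjusted R² = 1 − (1−R²)(n−1)/
(n−k−1); the shrinkage R² − adjusted R² serves as the cross-validation
index.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes, not the
full complexity of clinical imaging:

* **Template** — per hemisphere, six tube-like tracts on a 64×64×40 grid of
  2 mm isotropic voxels (small enough for seconds-scale tests, large enough
  for distinct tracts). Each tract is a stack of filled discs whose centres
  run linearly from a cortical seed (distinct (x,y) per area: preSMA most
  anterior/medial, S1 most posterior, PMD/PMV lateral) to a shared capsular
  convergence point, with radii shrinking linearly (4.5 → 2.0 voxels), so
  slice areas decrease toward the capsule and adjacent tracts overlap near
  convergence — mirroring the residual overlap of real fibre-tracking
  templates.
* **Lesions** — axis-aligned ellipsoids with centres concentrated in the
  deep territory lateral to the midline (x offset 16 ± 4 voxels, y 31.5 ±
  5, z uniform over the tract span) and radii uniform on 2–5 voxels.
  Real infarcts are not ellipsoidal and follow vascular territories; shape
  realism is a non-goal, coverage of the load distribution is the goal.
* **Cohort** — age from Normal(68, 10) truncated to [30, 95] (echoing the
  target population's median 68); affected hemisphere right with
  probability 0.7; one-week FM-UE from a U-shaped Beta(0.6, 0.8) scaled to
  0–66 (acute cohorts pile up at both floor and ceiling); NIHSS an
  independent Poisson(9) draw (joint NIHSS–FM structure is a non-goal). The
  six-month outcome is

      fmue_m6 = 27 + 0.45·fmue_wk1 − 0.05·wPMDLL − 3.5·1[age ≥ 70] + ε,
      ε ~ N(0, 3²),

  rounded to integers (the instrument is an integer scale) and clamped to
  [0, 66]. The generating w-PMD-LL is computed with the package's own
  scorer against the same atlas, so the emitted masks and the stored truth
  are internally consistent by construction — and a test re-derives the
  loads from the masks independently.

  The default coefficients put the three standardized effects in the order
  initial score (~9 points of outcome SD) > lesion load (~3) > age step
  (~1.6), clearly separated, and keep the linear predictor about three
  noise SDs inside the instrument range: clamping then remains a rare edge
  effect (measured 0 of 2000 subjects at defaults) so that ordinary least
  squares on the generated data is correctly specified — the property the
  parameter-recovery and bootstrap-coverage tests rely on. Consequently the
  synthetic full-model R² (~0.9 at n = 27) is cleaner than a real cohort's;
  passing tests demonstrate the estimators' correctness under the stated
  model, not clinical effect sizes.
* **Reproducibility** — every draw comes from `default_rng([seed, i])`,
  a per-subject counter substream: subject i's data are identical whatever
  the cohort size, and fixing the seed fixes every output bit-exactly.

## Numerical and scale choices

Test and acceptance problem sizes are picked to exercise each claim at the
smallest scale where the statistics are informative: 100 random mask pairs
for the per-voxel oracle; subset-R² equivalence up to p = 5 (oracle refits
grow as 2^p); 100 replications of n = 200 cohorts for selection and
coverage rates; B = 1000 resamples for demo bootstraps (matching the
standard choice) and B = 30 × 200 independent datasets for the
exchangeability average, where between-dataset variance, not
within-dataset resampling noise, dominates the Monte-Carlo error.

## Known limitations

* No registration or resampling: inputs must share a grid.
* Ellipsoidal lesions and tube tracts are geometric idealizations; the
  lesion-load *formula* is exact on any binary masks, but synthetic
  distributional results do not transfer to real cohorts.
* Durbin–Watson on cross-sectional data measures order structure in
  whatever case order is supplied; it is reported for completeness of the
  conventional battery, not as evidence of independence.
* At n = 27 the stepwise model may legitimately exclude the lesion-load
  predictor (its effect is small next to the baseline score); the pipeline
  reports what the data support rather than forcing the expected model.
* The exact-permutation Spearman option is limited to n ≤ 10 by cost.
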
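# Methods

## The model

The heat vulnerability index treats county-level vulnerability as a small
number of latent dimensions underlying ten observed percentage indicators.
Principal components of the indicator correlation matrix estimate those
dimensions; the Kaiser rule (eigenvalue > 1) decides how many carry more
variance than a single standardized variable; varimax rotation re-expresses
them in near-simple structure so each factor is interpretable through the
variables loading |λ| > 0.5 on it. Counties receive standardized regression
scores on each factor, each score is discretized into six SD-based categories,
and the categories are summed into the cumulative index. The additive,
unweighted sum embodies the assumption that the factors contribute equally and
independently to vulnerability — a deliberate, simple convention inherited
from the composite-index tradition rather than an empirical claim.

Urban and rural populations of the same counties are modeled as separate
strata throughout: indicator definitions coincide across strata (illiteracy
uses stratum-specific word-count thresholds) but the factor structure is
allowed to differ, and empirically does — illiteracy patterns with age and
disability among urban residents but with small dwellings among rural ones.

Assumptions worth making explicit: indicators are linearly related enough for
correlation-based extraction to be meaningful; higher values of every
indicator mean higher vulnerability (which justifies the positive sign
orientation below); and counties are exchangeable — no spatial autocorrelation
enters the model.

## Choice of correlation input

Published summary tables for the study region report Spearman correlations,
while conventional PCA operates on Pearson correlations of the raw
standardized data. The pipeline exposes this as an explicit parameter
(`pca_input`): runs from county tables default to Pearson; fixture-driven runs
necessarily use the transcribed Spearman matrices, the only quantitative
anchor available. For these data the two give closely similar spectra — the
retained-variance shares computed from the Spearman transcriptions (77.7%
urban, 76.6% rural) agree with the published values to one decimal.

## Rounding-aware Kaiser retention

Matrices transcribed from print are rounded to two decimals. Entrywise
rounding perturbs each off-diagonal by at most d/2 = 0.005, and by Weyl's
inequality eigenvalues move by at most the spectral norm of the perturbation,
bounded by its maximum absolute row sum (p − 1)·d/2 = 0.045 for p = 10.
`retain_factors` therefore accepts an eigenvalue tolerance;
`retention_tolerance(corr)` returns the Weyl bound when the matrix carries a
`print_precision` (all packaged fixtures do) and 0 otherwise. This matters for
the rural fixture, whose fourth eigenvalue is 0.9870: within rounding
uncertainty of 1, and retaining it reproduces both the documented four-factor
structure and the published variance share (top-4 = 76.6% vs. top-3 = 66.7%).
Matrices computed from data get no tolerance — the rule stays strictly
eigenvalue > 1.

The transcription itself is auditable: `data/transcription_manifest.csv` lists
all 90 off-diagonal cells with their printed token and recorded value. One
printed cell carries three decimals (0.403) and is kept as printed; one rural
cell (loss of labor ability × age ≥ 60, printed 0.04 with a p ≤ 0.01 star) is
internally inconsistent at n = 73 and is flagged as a suspected typo but
recorded as printed — substituting a plausible alternative (0.40) was tested
during design and fits the published variance share worse. Both fixtures are
positive definite; had tiny negative eigenvalues arisen from rounding, values
down to −1e-6 would be clipped to zero with a logged warning, and anything
below that rejected as an invalid matrix.

## Varimax

Rotation uses Kaiser's original pairwise planar algorithm: for each column
pair the closed-form angle `θ = ¼·atan2(D − 2AB/p, C − (A² − B²)/p)` exactly
maximizes the two-column criterion, so the criterion is non-decreasing at
every step (asserted by tests on the recorded per-sweep history). Sweeps stop
when a full sweep improves the criterion by less than `tol` (default 1e-6,
criterion units) or after `max_iter` sweeps (default 1000; non-convergence
sets a flag rather than raising). Kaiser row normalization — dividing loading
rows by their communality square roots before optimization — is ON by default,
the norm in this literature, and exposed as a flag. Because rescaling commutes
with column rotations, the final loadings are always `L·R` for the original L,
so row communalities are conserved to machine precision regardless of the
normalization setting.

Two presentation conventions are applied after rotation and logged: each
factor column is flipped so its largest-|loading| entry is positive (all
indicators are coded higher-is-more-vulnerable, so positive orientation makes
higher scores mean higher vulnerability and keeps the additive index
directionally coherent), and columns are reordered by descending explained
variance. Eigenvector signs in the unrotated solution follow the same
largest-component-positive rule, making the decomposition deterministic.

## Factor scores and binning

Scores use the regression (Thurstone) estimator `W = R⁻¹L` on column-
standardized data; the scoring matrix must be the Pearson correlation of the
same table and is rejected if its condition number exceeds 1e8 (near-collinear
indicators make the weights meaningless before they make the solve fail).
Score columns are re-standardized to mean 0 and sample SD exactly 1 — the SD
convention is n−1 throughout the package, the usual convention for
census-derived summaries.

The six categories partition the real line with no gaps: the outer bounds are
closed (z = ±2 land in categories 1 and 6), negative inner boundaries assign
outward (z = −1 → 2), and non-negative boundaries assign upward (z = 0 → 4,
z = 1 → 5). The source convention specifies only the outer bounds; this
completion is symmetric at ±2, puts the mean in category 4, and is logged
whenever a county lands exactly on an inner boundary so the (measure-zero, but
real under rounding) sensitivity is visible. "Above the mean on all factors"
uses strict positivity, since standardized scores have mean exactly 0.

## Synthetic counties

The generator draws latent scores F (n × 4 independent standard normal),
residuals E with per-variable uniqueness SD, forms
`Z = (F·Lᵀ + E) / sqrt(communality + uniqueness²)` and maps to percentages via
the published per-stratum means and SDs. Defaults are the study conditions:
n = 73 counties, four single-salient-loading blocks (poverty ×3,
elderly/fragile ×2, isolation ×2, dwellings ×2, with illiteracy joining the
elderly block in the urban preset and the dwelling block in the rural one),
salient loadings 0.70–0.85 — the band typical of published rotated solutions
in this literature — and uniqueness SD 0.3. Latent factors are orthogonal in
expectation only, as in finite census samples. Clipping to [0, 100] is ON by
default so generated tables satisfy the percentage schema, and OFF in recovery
benchmarks because truncation attenuates correlations.

What the generator does **not** emulate: spatial autocorrelation between
neighboring counties, the skewness and heteroscedasticity of real
administrative rates (variables are conditionally Gaussian), cross-loadings,
and any dependence between the urban and rural strata of the same county.
Passing recovery tests therefore show the estimator chain is correct under its
own model, not that four factors is the right description of any real region.

Recovery is measured by the mean matched Tucker congruence: |cosine| between
true and estimated loading columns, maximized over the k! column matchings
(signs absorbed). Benchmarks use n = 200 rather than 73 to separate method
error from small-sample noise; at the default noise level mean congruence
exceeds 0.99, and it degrades monotonically as uniqueness grows.

## Pipeline and reproducibility

A run processes each stratum through correlation → extraction → retention →
rotation → scoring → index, writes delimited-text reports plus a JSON manifest
(config, seed, software version) sufficient to re-execute it, and finishes
with a cross-stratum comparison (medians, ranges, above-mean counts, per-area
means, counties with equal urban and rural index). Fixture mode stops after
the loading/variance stage: factor scores require county microdata that are
not public, and fabricating them would imply false reproducibility. In
synthetic mode the two strata use seeds `2s` and `2s+1` derived from the
user's seed, so they are independent but jointly reproducible; outputs are
byte-identical across re-runs of the same config.

The optional GeoJSON export joins cumulative index values onto user-supplied
county features by a configurable property key; no boundary data is bundled
and no cartography is attempted.

## Known limitations

- Equal factor weighting and SD binning discard information; counties near
  category boundaries can move a whole integer under tiny data perturbations.
- The Kaiser rule is the only retention rule offered (no parallel analysis or
  scree criteria), matching the method being reproduced rather than best
  current practice.
- Only orthogonal rotation is supported; correlated vulnerability dimensions
  would call for oblique methods out of scope here.
- Exact per-county published index values are not reproducible without the
  census microdata; the package reproduces the published factor structure and
  variance shares, and the index machinery is validated synthetically.
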
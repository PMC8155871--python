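# Methods

## Colour measurement and segmentation

Input photographs are assumed to be standard sRGB captured under a D65/2°
illuminant (the light-cabinet setting the workflow targets). No camera
characterisation profile is applied: a calibrated-camera transform is
instrument-specific and unavailable in general, so the standard
sRGB → linear RGB → XYZ → CIELAB chain is used instead. The conversion
matrix is the high-precision sRGB matrix and the reference white is defined
as the matrix applied to RGB (1,1,1), making the chain self-consistent: the
white point maps exactly to L\* = 100, a\* = b\* = 0. Chroma and hue follow
the usual polar form; the hue of the achromatic origin is 0 by convention.

Seeds are dark objects on a light plate, so segmentation is a global
threshold on the lightness channel (default: fixed at 0.75 of full scale;
Otsu is available via `threshold_mode="otsu"`), followed by 8-connected
component labelling. Components smaller than `min_area_px` (default 30 px)
are dropped with a warning. Grid assignment divides the image evenly into
`grid_rows × grid_cols` cells and assigns each region to the cell containing
its centroid; two centroids in one cell raise an ambiguity error rather than
guessing. Per-seed colour is the arithmetic mean of per-pixel CIELAB values
(CIELAB, not RGB, because CIELAB is the measurement space of the analysis);
chroma and hue are recomputed from the averaged a\*, b\* so each record
satisfies C\*ₐᵦ = √(a\*² + b\*²) exactly.

The ellipsoid fit minimises the algebraic residual of x'Ax + 2b'x = 1 over
the nine quadric coefficients (≥ 9 points in general position required),
then extracts centre, semi-axes and orientation from the eigendecomposition.
The reported residual is the RMS radial distance from the points to the
fitted surface. The fit is exposed as a standalone morphology utility; it
plays no role in staging.

## Staging

Both L\* and C\*ₐᵦ fall as seeds ripen, and neither alone is privileged, so
the default ripeness score is the projection of the standardized (L\*,
C\*ₐᵦ) pairs onto their first principal axis, signed so that the score rises
as L\* falls (darker = riper). Single-axis modes (`"L"`, `"C"`) are
available. Percentile classification sorts by score with a stable tie-break
on seed id and splits into k contiguous groups whose sizes differ by at most
one (equal when k divides n); stage 1 takes the lowest scores. Percentiles
are computed over the pooled collection, not per sampling date. The
sensory/texture split is stratified by stage with largest-remainder
allocation and a seeded RNG.

## Texture parameter extraction

Traces are trimmed to the triggered portion (force ≥ 0.049 N ≡ 5 g),
re-zeroed at the trigger, and truncated at maximum distance to discard the
probe-retract tail. Time-mode files are converted with distance =
time × probe speed.

Event detection runs on a smoothed copy (centred moving average, default
window 5 samples ≈ 0.01 mm at the default acquisition settings, shrinking at
the ends); peaks are local maxima with prominence ≥ `min_prominence`
(default 2 N). The break is the first peak whose force falls, before the
next peak, by at least `drop_fraction` (default 20 %, configurable — the
qualitative criterion is a rapid collapse) of the peak force.

Parameter values are then measured on the **raw** trace: the break index is
refined to the raw argmax within half a smoothing window of the smoothed
peak, and Bf, Bdc, the 10 N-floor elasticity regression and the trapezoidal
energies are computed from raw samples at those locations. Smoothing biases
an apex downward, so measuring on the raw curve keeps noise-free extraction
exact while detection stays noise-robust. The 10 N crossing uses the first
sample at or above 10 N (no sub-sample interpolation). Energies are N·mm,
reported as mJ with no conversion factor. Si and Ar are stored as fractions
of 1 (e.g. 0.24), matching how stage summary tables print them, although
both are conceptually percentages. Curves with no qualifying break are
flagged and excluded rather than forced into a profile.

## Panel statistics

The three-way ANOVA is the balanced fixed-effects decomposition (judge,
session, sample, all two-way interactions). With one observation per
judge × session × sample cell the three-way interaction is confounded with
error and is used as the error term. Balance is enforced: missing or
duplicated cells raise an error naming them. In the balanced case Type I and
Type III sums of squares coincide; the closed-form cell-mean decomposition
is used (it matches `statsmodels.anova_lm` to machine precision in the test
suite) because the Monte-Carlo calibration runs thousands of fits. Scores
are treated as continuous despite the structured 0–10 scale. When nothing
varies, F is reported as NaN (not applicable) rather than 0/0.

SNK uses numerically computed studentized-range quantiles (memoised — the
distribution is expensive to evaluate) with the standard protection rule:
ranges inside a non-significant stretch are never declared different.
Letters are the maximal non-significant intervals in ascending-mean order,
so two groups share a letter exactly when the procedure does not separate
them. Unequal group sizes use the harmonic-mean n.

The homogeneity PCA takes the samples × judges matrix of session-averaged
scores, standardizes columns, and diagnoses `scale_effects` when all judge
loadings on PC1 share a sign and PC1 explains at least 60 % of the variance
(configurable); otherwise `disagreement`. Judge screening averages each
judge's within-(sample, attribute) score variance across sessions and flags
judges more than 1.5 panel SDs above the panel mean (the multiple is
configurable because no standard cutoff exists); screening refuses to shrink
the panel below three judges.

## Integration

Headline correlations and the PCA are computed on the stage × variable mean
matrix (five observations), matching how such results are reported; per-seed
matrices are also accepted. Redundancy pruning processes pairs with
|r| > 0.80 greedily in decreasing |r| and drops the variable ranked later in
a priority list; the default list ranks the derived quantities Be and Ar
last, operationalising "keep the variable that is easier to interpret"
(prefer Bf and Bd over Be, Si over Ar). Report output rounds half-up to two
decimals. The PCA standardizes columns (ddof = 1), so eigenvalues are those
of the correlation matrix and Kaiser's eigenvalue > 1 rule applies directly;
with five stage means at most four components are non-null and they carry
100 % of the variance.

## Synthetic data

The generators define the study conditions for all tests:

* **Images** — 12 × 8 grid, 40 px cells, light-gray plate (RGB ≈ 235, fixed
  rather than modelled), elliptical seeds with jittered geometry. Stage
  colours walk from greenish-light (L\* 62, C\* 36, h 95°) to dark brown
  (L\* 32, C\* 14, h 58°) with per-seed SDs (2.0, 1.5, 3.0) and per-pixel
  Gaussian noise (SD 2.5 8-bit counts). Stages tile the grid in contiguous
  near-equal blocks so percentile staging can be scored against truth.
* **Curves** — piecewise-linear templates: rise at slope E to (Bd, Bf), a
  0.04 mm collapse of Bdc, a short valley floor, Np − 1 subfragmentation
  bumps climbing back toward Bf, stop at Th/2. Knots snap to the 0.002 mm
  acquisition grid so the trapezoid rule is exact and the analytic profile
  is the extraction oracle. Per-stage parameter means/SDs follow the
  published Syrah stage table; draws are clipped to physically consistent
  ranges (e.g. Bdc ≥ 0.3 Bf so a break exists, the break inside the first
  half of the stroke). Force noise defaults to SD 1 N.
* **Scores** — score = clip(gain_j × stage_mean + bias_j + ε, 0, 10) with
  positive judge gains (SD 0.12), biases (SD 0.5) and residual SD 0.8; the
  session main effect is zero by construction, and `sample_effect=False`
  gives the ANOVA null. Default stage means rise for colour/hardness/
  cracking and fall for vegetal/bitterness/astringency; effect sizes keep
  means ≈ 2 SDs clear of the scale bounds so clipping stays negligible.

What the simulators do **not** emulate: real seed shapes and gloss, seed
touching/occlusion, camera vignetting or calibration drift, visco-elastic
curvature and load-cell drift in the traces, attribute-to-attribute score
correlations within a judge, or panel learning across sessions. Passing
recovery tests therefore shows the algorithms are correct on data with the
declared structure, not that the defaults are optimal for any particular
instrument.

## Problem sizes and determinism

The test suite uses one 96-seed image, cohorts of 50 noise-free and 200
noisy curves, 1000 ANOVA replicates for the null calibration (8 judges × 4
sessions × 5 stages per replicate), and a full simulated run with 20–50
curves and an 8-judge panel — sizes chosen to estimate each rate stably
while keeping a laptop run in seconds. Every stochastic step takes a numpy
`Generator`; fixed seeds make images byte-identical and pipeline summaries
byte-identical on re-runs.

## Known limitations

* Staging polarity assumes the darkening-with-ripeness direction; an
  atypical palette would need the single-axis modes or a sign override.
* The ANOVA is fixed-effects; judges are not modelled as random draws from a
  population, so conclusions are conditional on the panel.
* The break rule (20 % relative drop) is a quantification of a qualitative
  criterion; very ductile seeds with gradual yield may be flagged as
  no-break.
* Correlations on five stage means have wide sampling error; printed
  two-decimal agreement with recomputed values can differ in the last
  decimal because published means are themselves rounded.
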
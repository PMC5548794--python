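# Methods

## Coordinate frame and conventions

All per-specimen geometry lives in a cylindrical frame around the modiolar
axis. The angular position α is measured from the basal starting point
(the first measured point, near the round window); the internal angle unit
is **radians** everywhere, because polynomial coefficients are
unit-dependent and a single internal unit prevents silent rescaling. Table
I/O and reporting use degrees; angular-length regression and its residuals
use turns. Heights are anchored at the base — h(0) = 0, positive toward
the apex — so a "sloping" profile is increasing and a "rollercoaster" dip
is a negative excursion. The shift from an apex-anchored to a
base-anchored origin is a constant and does not affect any coefficient of
degree ≥ 1.

The canonical chirality is left-handed (x = cos α·r, y = +sin α·r);
right cochleae mirror y → −y. Since r(α), h(α), the base parameters and
all lengths are mirror-invariant, canonicalisation only annotates the
record; the sign enters when a 3D curve is composed or exported.

## Per-specimen fits

The logarithmic spiral is fitted by OLS on (α, log r) — the linearised
form — not by nonlinear least squares in mm. This is the standard
linearisation and makes the fit a closed-form linear solve; the objective
actually minimised (log-space SSR) is stored alongside the model-space
residuals in mm that all comparisons use. The cubic radius and quartic
height fits are OLS on the raw monomial bases. Because α spans ~0–18 rad,
all polynomial solves go through an orthogonalised fit on a scaled domain
(`numpy.polynomial.Polynomial.fit`) and the coefficients are converted back
to the raw basis; raw normal equations at degree 4 lose ~10 digits of
conditioning on this domain. Repeated α values are allowed; only the
count of *distinct* angles must meet the minimum (2 for the log spiral, 4
for the cubic, 5 for the quartic). Absent samples (NaN) are skipped.
Samples are unweighted.

## Population model

Each coefficient (and the angular length in turns) is regressed
independently on the predictors (1, A_a, B_a, A_b, B_b) — the model is
exactly this separable stack of univariate-response OLS problems, so the
trained object is a set of matrices (5×4 radius, 5×5 height, 5×1 angular
length; 5×2 for the logarithmic variant, whose regressed coefficients are
(log a₀, a₁)). No shrinkage or multivariate coupling is applied: the point
of the model is the plain linear dependence, not an improvement on it.
Training requires ≥ 5 records and a full-rank predictor design; collinear
predictors are named in the error.

A prediction with angular length ≤ 360° or a non-positive radius anywhere
on its domain is **flagged and returned**, never clamped: there is no
principled clamping rule, and silently correcting implausible predictions
would bias validation residuals.

## Arc length

Metric length is the arc length of the parametric curve, i.e. the integral
of √(r′² + r² + h′²) dα (h′ omitted when the planar length is requested).
The integrand is smooth, so adaptive Gauss–Kronrod quadrature with absolute
tolerance 10⁻⁸ mm is used, subdividing once per turn so the adaptive rule
spends its interval budget locally. Closed forms for circles, helices and
logarithmic spirals, plus a 10⁶-segment polyline summation, serve as
independent oracles in the tests.

## Validation

Prediction quality is evaluated at the 90° nodes of each specimen's
angular length. Measured node values are linearly interpolated from the
sampled profile when no sample falls on a node; nodes beyond the
specimen's own length are absent and contribute nothing (no imputation) —
per-specimen SSRs are plain sums over available nodes. LOOCV retrains the
model once per held-out specimen and predicts it from its base parameters
alone; the mean squared LOOCV residuals are the maximum-likelihood
estimates of the prediction MSE per quantity. Model comparison sums
squared node residuals per specimen and applies a two-sided paired t-test
and Wilcoxon signed-rank test (α = 0.05, no multiplicity correction) with a
t-based 95 % CI; differences and the SSR ratio are reported as second
argument over/minus first.

## Derived morphometrics

- **Wrapping factor** = angular length / metric length (°/mm); the
  basilar-membrane wrapping ratio is 0.87·metric/angular (mm/°).
- **Radii ratio** = base radius / apex radius. The base radius is the mean
  of samples in [0°, 90°] and the apex radius the mean over the final 90°
  of the measured profile. *This windowing is a package convention*: the
  original single-point definition is not fully specified, and window means
  are robust to single-sample noise. Consequences: the ratio depends on
  the sampling grid, and with a decaying spiral it increases with angular
  length at fixed decay rate (a closed-form property the tests check).
- **B-ratio** = B_a/(B_a+B_b); ratio_A = A_b/A and ratio_B = B_b/B are kept
  under separate names because B-ratio and ratio_B are complementary and
  quartile order reverses between them.
- **Base area** uses the ellipse approximation π·(A/2)·(B/2); the exact
  planimetric definition is not reproducible from the base axes alone.
- **Vertical profile**: rollercoaster iff the minimum height within
  (180°, 360°] lies more than a depth threshold below h(0) *and* a later
  sample rises more than the threshold above that minimum; default
  threshold 0.1 mm (the order of measurement resolution), exposed as a
  parameter. Ties and sub-threshold dips classify as sloping; the
  classification is invariant to adding a constant to all heights.
- Quartile groups sort by (value, id) — id as deterministic tie-break —
  and split into four nearly equal groups; the correlation screen uses
  pairwise-complete Pearson r with two-sided p, cells with < 3 complete
  pairs undefined.

## Synthetic populations

The generator draws base parameters from a multivariate normal
(means 5.3/3.7/3.5/3.3 mm for A_a/A_b/B_a/B_b, SDs 0.45/0.35/0.30/0.30,
common correlation 0.4) and derives every per-specimen coefficient from the
same linear law the prediction model assumes, so pipeline closure and
parameter recovery are exact when noise is zero. Gaussian noise (defaults:
radius 0.05 mm, height 0.1 mm — the scale of careful microscope
measurements) is added to samples on a 90° grid (configurable down to 10°)
up to each record's own angular length; samples beyond it are absent, as in
real measurement tables. Specimens are rejection-resampled when a base
parameter is non-positive, the angular length leaves [2.05, 2.95] turns, or
the radius law dips non-positive on the specimen's domain.

The default generating matrices are assembled from documented anchor
quantities rather than opaque numbers: the typical radius cubic solves
r(0) = 5.4 mm, apical-window mean 0.632 mm, ∫r dα = 40.5 mm·rad and end
slope −0.04 mm/rad at the reference length of 2.45 turns; its intercept
scales with A_a and B_a at 0.17 mm/mm. The height law is a quadratic
ascent to 2.4 mm plus a quartic dip bottoming at 270°, whose amplitude
grows with B-axis asymmetry (B_b − B_a) at strength
`rollercoaster_coupling`; the angular length decreases with total base size
at `wrapping_area_coupling` (−0.10 turns/mm). These anchors were
calibrated once, by Monte-Carlo at n = 500 over several seeds, to the
published population envelopes: metric lengths ≈36–46 mm, ≈200°
angular-length spread at study scale (n ≈ 108), radii-ratio mean ≈7.57,
roughly half the specimens rollercoaster, and a strongly negative
wrapping–base-area correlation.

What the generator does **not** emulate: per-specimen deviations from the
linear coefficient law (real coefficients scatter around any population
law), non-Gaussian or angle-dependent measurement error, the vertical jump
where the second turn meets the first, the basal indentation near the
facial nerve, or left/right asymmetries. Passing tests therefore
demonstrate correctness of the machinery and the direction of effects under
the model's own assumptions — not that real cochleae follow a cubic law.
Two known departures from published values: the synthetic radii-ratio
spread (SD ≈ 3) exceeds the reported ≈1.5, because the window-mean apex
radius rests on one or two 90°-grid samples; and the generated
wrapping–area correlation (≈ −0.98) is stronger than reported (−0.77),
because the generated angular length is an exact linear function of base
size.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at n = 20 (noiseless
closure), n = 50–60 (noise floor, model comparison over 10 seeds), and
n = 200–500 (calibration and correlation checks) — sizes at which every
quantity of interest is stable while a full run stays in the minutes range
on one core. Coefficient-recovery assertions use 10⁻⁶–10⁻⁸ relative
tolerances (the conditioning limit of degree-4 fits on an 18-rad domain);
arc lengths are checked to 10⁻⁶ mm against closed forms. Degenerate
comparison inputs (zero-variance paired differences) yield NaN test
statistics rather than raising.
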
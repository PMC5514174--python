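# Methods

## Scene model

Scenes are flat-shaded compositions on a vertical sky/ground gradient:
a person (body + head, with a face disk), a building (with window
panes), a vehicle and a tree, each standing on the ground plane.  A
single light azimuth θ (degrees; 0 = up/north, 90 = right/east) drives
every cast shadow: the object's footprint segment is translated by
L·(−sin θ, 0.35 + 0.25·cos θ) with L = 0.6 × object height, and the
resulting quadrilateral is darkened by a flat factor (0.55 by default,
no penumbra).  Objects are drawn after shadows and therefore occlude
them.  Rendering is pure array arithmetic, so a spec renders to
byte-identical 8-bit RGB every time — which is what makes the
manipulation masks exact: the mask of a stimulus pair is *defined* as
the set of pixels whose stored 8-bit values differ.

Default canvas sizes are 400×300 with a 3×3 grid (detect-first design)
and 480×320 with a 3×4 grid (locate-always design).  These are
desk-scale stand-ins for megapixel photographs; every statistic in the
package is resolution-relative (means over pixels, proportions over
regions), so nothing downstream depends on the absolute size.

### Manipulations

* **airbrush** — blend the face disk toward a Gaussian-smoothed,
  slightly brightened copy; strength sets the blur width and blend
  weight.  Deliberately the subtlest change.
* **addsub** — remove a tree/vehicle (region = object ∪ its shadow,
  filled with the median colour of a 6-px border ring) or insert a tree
  with its shadow at a clear location.
* **geometry** — re-render with the top half of a building sheared
  horizontally (slope ∝ strength): a physically implausible wall.
* **shadow** — re-render with one object's shadow deleted or reflected
  to the wrong side of the light.
* **superadditive** — all four at once on pairwise-distinct targets
  (face, removable object, building, and a different shadow caster);
  components are computed against the same original and pasted by
  mask, so the component masks are pairwise disjoint and mean ΔE is
  exactly additive (the property the name promises).

Geometry and shadow manipulations are produced by re-rendering a
modified scene rather than by pixel surgery; determinism of the
renderer makes the diff mask exact, and the referenced object's pixels
are kept as an *evidence mask* for the liberal scoring criterion below.

### Grid-span calibration

The set builder targets a mean of 2.0 mask-covered grid regions per
manipulated image (tolerance ±0.5), matching the design intent that a
manipulation spans about two cells.  A global extent scale multiplies
object sizes; after each candidate set the builder measures the mean
span and retries with scale × (target/actual)^0.7, bounded to
[0.35, 2.5] and at most 8 attempts before raising a calibration error
with its history.  The default strength schedule orders mean ΔE as
airbrush < {addsub, geometry, shadow} < superadditive; a test asserts
the ordering on generated sets.

## Colour metric

sRGB is decoded with the standard two-part gamma, taken to XYZ with the
D65 matrix and to CIE L\*a\*b\* against the D65/2° white (the white
point equals the matrix row sums, so RGB 255 maps to L\* = 100
exactly).  ΔE₇₆ is the per-pixel Euclidean distance in L\*a\*b\*, and an
image pair's score is the mean over *all* pixels, not just the mask —
the whole-image average is what a screening metric sees.  The log
transform defaults to base 10 and is undefined (error) at ΔE = 0.
Scores are computed on the stored 8-bit images, so quantization is part
of the metric.  The conversion is cross-checked in the tests against
scikit-image's colorimetry to |Δ| < 0.01.

## Localization scoring and chance

Grid cells are half-open row-major intervals; a boundary pixel belongs
to the cell containing its top-left coordinate.  A region counts as
manipulated as soon as one mask pixel falls in it (a coverage-fraction
threshold is available).  The *majority* region (largest mask pixel
count, ties to the lowest index) is what an ideal locator answers.

The liberal criterion scores a response as correct in any *acceptable*
region: the manipulated regions plus — for the shadow and geometry
classes, whose evidence (the object with the wrong shadow, the sheared
building) can sit outside the changed pixels — regions containing
evidence-object pixels that share an edge with a manipulated region.
The policy is pluggable (`mask_only` disables the extension).

Chance has three estimators that a test ties together: analytic
mean(k)/R for acceptable counts k on an R-region grid; a Monte Carlo
that samples an image uniformly then a region uniformly (10⁶ draws by
default, binomial normal CI); and an empirical baseline from guesses on
original images (fraction landing in each type's acceptable set, with
row/column means).  Percentages are rounded half away from zero to
whole percent, matching how such tables are printed.

## Observer model

Per trial, with x = log₁₀ ΔE and x₀ a centring constant:

    P(yes | manipulated) = logistic(γ₀ + γ₁(x − x₀) + covariates + w·e)
    P(yes | original)    = logistic(γ₀ + covariates + w·e)
    P(locate = majority | manipulated) = (1 − λ) · logistic(δ₀ + δ₁(x − x₀) + covariates)

with everything else — original-image guesses, lapses — drawn from a
centre-biased region-popularity weight vector.  e ~ N(0,1) is a
per-trial attentiveness draw shared with the log-normal response-time
model (log RT = μ − 0.35·e + σ·ε, scaled per subject), so attentive
trials are simultaneously faster and more accurate; that single latent
is what produces the RT-octile effects the covariate models find.  The
three-option detection answer ties "yes, I can see where" to the
localization success draw.

Defaults (γ₀ = −1.1, γ₁ = 1.2, x₀ = −2.2, δ₀ = −0.7, δ₁ = 0.8,
λ = 0.1, belief effect +0.15 log-odds) were calibrated once so the
synthetic headline results sit near the human descriptive values
(~60–66% detection accuracy, F ≈ 0.28, positive ΔE–accuracy
correlation); they are generative defaults, not targets, and every test
either fixes its own parameters or checks structure rather than
headline magnitudes.

Sessions give each subject 10 distinct scenes, half original and half
manipulated with the five types cycled, never the same scene twice.
Per-subject random streams are split from one root seed by subject
index, so enlarging the panel never reshuffles existing subjects.

### What the generator does and does not emulate

It emulates: graded detectability in physical change, response bias,
subject covariate effects, RT–accuracy coupling, non-uniform guessing,
the two designs' locate-when rules.  It does not emulate: saliency or
attention maps, learning across trials, photographic texture, JPEG
re-compression noise (a flag exists but defaults off), or the
demographic structure of a real panel.  Passing tests therefore show
the *analysis chain* is correct and recoverable on data with known
ground truth — not that humans behave like the generator.

## Estimation choices

* d′/c: boundary rates corrected by 1/(2N); CIs by percentile bootstrap
  over subjects (2000 resamples by default, seeded).  Both the
  aggregate-rate and the mean-of-subject-level estimates are reported —
  they differ by Jensen-type averaging, and the package treats the
  subject-level ones as the modelling outcomes.
* GEE: estimation delegates to statsmodels (binomial or Gaussian
  family; exchangeable working correlation by default, independence for
  cross-checks) with robust sandwich errors.  Factors are reference-
  coded against male / low-belief / not-interested /
  monthly-yearly-never; RT octiles enter as a numeric 1–8 level
  (slowest = 1).  |B| > 15 on the logit scale is flagged as separation.
  The location model in the detect-first design uses only the trials
  that have a location response (the "no" trials have none), and its
  default predictor set drops RT accordingly.
* Correlations: image-level n = 30 manipulated images; type-level
  (n = 5) correlations are computed but treated as descriptive.  The
  one-tailed Fisher p is reported alongside the two-tailed.
* Recovery suites simulate from the model being fitted: the GEE
  coverage/recovery runs set the signal slope and attentiveness to zero
  because a marginal logistic coefficient is non-collapsible under a
  large omitted signal term — with the default γ₁ the fitted belief OR
  attenuates by ~20%, which is a property of marginal models, not an
  estimation defect.

## Problem sizes and determinism

The shipped tests run 6–10 scenes per set, 40–600 subjects per
simulation, 10⁶ Monte Carlo draws, 50-run GEE coverage suites and
100–200 bootstrap resamples — sizes chosen so the whole suite completes
in a few minutes on one core while keeping every statistical check at
3σ-style resolution.  All randomness flows from explicit seeds
(`numpy` `SeedSequence` spawning per stage and per subject); the
pipeline's JSON summary is byte-identical across reruns of the same
config and seed.

## Known limitations

* The acceptable-region "evidence" policy is one reasonable
  operationalization of a criterion that real studies apply by hand;
  published per-type chance tables cannot generally be reproduced from
  mask counts alone, and the package anchors its checks on conditions
  where the analytic rule is exact.
* Aggregate-rate d′ differs from a mean of subject-level d′ values;
  when comparing to published figures, know which one a paper prints
  (the criterion c typically matches the aggregate computation, d′ the
  subject-level mean).
* Flat-shaded scenes make ΔE values small in absolute terms compared
  with textured photographs; only relative/ordinal ΔE structure should
  be interpreted.
* The insertion variant of add/sub can fail on crowded canvases (no
  free lane), which surfaces as an unsupported-manipulation error
  rather than an overlapping stimulus.
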
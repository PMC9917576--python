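# Methods

## Problem and scope

`skinaging` quantifies visible facial skin aging from calibrated close-up
RGB photographs. Four object classes are detected and measured inside a
region of interest (ROI): **wrinkles** (long, thin, dark curvilinear
structures), **hyperpigmented spots** (large irregular dark patches),
**texture/roughness elements** (small compact contrast elements) and
**pores** (small, irregular, high-contrast openings). Their summed pixel
areas, normalised by the ROI area, give per-image *area fractions*; ROI
colour is summarised as mean CIELAB lightness (L\*), redness (a\*) and
yellowness (b\*). Longitudinally, the wrinkle, spot and roughness fractions
are combined into an *Overall Skin Aging Score*, and treatment-induced
change in that score is expressed as *reversal years of skin aging*.

Since clinical photographs of this kind are not publicly distributable, the
package ships a synthetic-image and synthetic-cohort generator that renders
ground-truthed objects and simulates an 86-subject, five-visit cohort with
the statistical structure the analysis assumes. Every pipeline stage is
validated against that ground truth.

## Image analysis

### Colour model

All colour arithmetic is done in CIELAB (sRGB primaries, D65, 2° observer
assumed on input; no colour profile handling). Colour difference is CIE76,
the Euclidean distance ΔE = ‖(ΔL\*, Δa\*, Δb\*)‖ — the simplest and
era-appropriate reading of "ΔE". Redness and yellowness map to the a\* and
b\* axes, the only CIELAB axes matching those words. Images are carried as
float sRGB in memory and quantised only on export (8-bit PNG or 16-bit
TIFF); this keeps small planted colour offsets exact, since 8-bit
quantisation alone can shift a region's mean a\*/b\* by up to ~0.4 units.

### Candidate extraction

The segmentation operator is deliberately simple and isolated behind a
config: a smooth background field is estimated by Gaussian smoothing at a
scale (default **10 mm**) at least twice the largest class-defining size
(5 mm), so genuine features are not absorbed into the background. For
speed the smooth is computed on a 4× downsampled pyramid level (σ/4) and
upsampled; this is numerically equivalent to the direct large-kernel filter
to well below the noise floor. Pixels whose CIE76 ΔE from the background
field exceeds the candidate threshold (default **1.5**, the smallest class
threshold, so no class-eligible object is lost at candidacy) are kept,
cleaned by a 1-px-radius morphological opening, and labelled with
8-connectivity inside the ROI. Components touching the ROI border are
flagged and excluded from area fractions by default (their shapes are
clipped).

### Shape descriptors

For each connected object:

* **area** — pixel count; mm² through the single calibration constant
  `mm_per_px` (default **0.1 mm/px**, a realistic close-up facial capture
  scale; every mm-denominated rule converts through it).
* **perimeter** — a weighted walk along the traced (Moore-neighbour) outer
  boundary. The default weights are the corner-corrected set
  (0.980/edge step, 1.406/diagonal step, −0.091/direction change), which
  are nearly unbiased on digitised smooth contours: a digital disk of
  radius 30 px measures circularity 12.53 against the isoperimetric
  minimum 4π ≈ 12.57. The classical 1/√2 chain weights
  (`perimeter_scheme="chain"`) are kept selectable but overestimate curved
  boundaries by ~5.5%, which squares to ~11% on circularity.
* **length** — the longest geodesic path through the morphological
  skeleton (edge steps 1, diagonal √2, plus one pixel for the end-pixel
  extent), i.e. the arc length of a curvilinear object rather than its
  caliper diameter. Under arc length, a thin curve has perimeter/length
  ≈ 2, which is what makes the wrinkle rule's perimeter/length ≤ 2.5
  cutoff interpretable for curved wrinkles.
* **aspect ratio** — major/minor axis of the second-moment-equivalent
  ellipse (≥ 1 by convention).
* **circularity** — perimeter²/area, minimised at 4π by a disk.
* **surround ΔE** — CIE76 distance between the object's mean Lab and the
  mean Lab of a surrounding annulus (mask dilated by a disk of the ring
  width, default **1.0 mm** — comparable to the smallest feature scale yet
  wide enough to average noise — minus the mask), excluding pixels of
  other detected objects so nearby or nested objects do not contaminate
  the background estimate.

Single-pixel objects are flagged degenerate (length = `mm_per_px`, aspect
ratio 1) rather than erroring.

### Classification rules

Rules are applied with inclusive comparisons, in the fixed precedence
order **wrinkle → spot → pore → texture** (most to least specific; the
ordering also resolves the pore/texture overlap — a small compact object
with ΔE ≥ 2 and circularity ≥ 20 satisfies both printed rule sets — in
favour of the stricter class):

| class   | rules |
|---------|-------|
| wrinkle | length ≥ 5 mm, perimeter/length ≤ 2.5, circularity ≥ 34 |
| spot    | area ≥ 5 mm², surround ΔE ≥ 3, circularity ≥ 20 |
| pore    | area ≤ 4 mm², surround ΔE ≥ 2, circularity ≥ 20 |
| texture | area ≤ 3 mm², aspect ratio ∈ [0.5, 2], surround ΔE ≥ 1.5 |

All thresholds are parameters of `SkinObjectClassifier` (an sklearn-style
estimator) and of the YAML `RunConfig`, with the printed constants as
defaults. Note the circularity ≥ 20 floor for spots and pores exceeds the
theoretical disk minimum 4π ≈ 12.57: under any near-unbiased perimeter
estimator, *smooth* round blobs can never satisfy it, so these classes
implicitly require irregular boundaries. The estimator behind circularity
is therefore documented and configurable, and the synthetic spot/pore
shapes carry boundary modulation (below).

### Fractions and scores

Per class, fraction = Σ area(px) of that class / ROI(px); the pore
fraction carries a conventional ×3 multiplier (range [0, 3]). Wrinkle,
spot and roughness fractions are min–max scaled to [0, 1] over the pooled
subject × timepoint table (`AgingScoreScaler`; the fitted bounds are
exported so the scaling is reusable and replaceable), and the Overall Skin
Aging Score is their per-observation sum (0–3). Cohort averaging happens
afterwards, in reporting.

**Reversal years**: with S(t) the overall score at follow-up, S₀ the
pre-treatment score and S₋ the score measured `interval_years` earlier
(default **11**),

    years(t) = interval_years · (S(t) − S₀) / (S₀ − S₋)

so years = 0 at S(t) = S₀ and −11 at S(t) = S₋. The sign convention is
anchored so that recovery toward the earlier baseline is negative
("years reversed"). The estimate is affine-invariant in the three scores
and undefined (raised as an error) when |S₀ − S₋| < 10⁻⁶ — a subject who
did not age on this score has no reversal scale. Because it is a ratio
estimator, per-subject values are heavy-tailed whenever the measurement
noise is comparable to a subject's own decade-scale aging; cohort means
of reversal years are therefore only stable when the aging signal
dominates (the synthetic low-noise configurations make this explicit).

## Statistics

Tables are tidy `(subject_id, timepoint, parameter, value)`. Paired
contrasts are complete-case paired t tests (two-sided, df = n − 1; a
constant difference is flagged degenerate with p reported as 0 or 1
rather than a division by zero). Correlations are sample Pearson r with
the two-sided t-based p on n − 2 df (`scipy.stats`). No multiple-testing
correction is applied and no mixed-effects modelling is attempted; the
summary layer reports per-parameter mean ± sample SD (ddof = 1) per
timepoint with paired p against the decade-earlier baseline and the
pre-treatment visit.

## Synthetic data

### Images

Background: uniform CIELAB skin colour (default L\* = 59.27, a\* = 12.55,
b\* = 20.39, a measured healthy-skin facial colour) with i.i.d. Gaussian
noise of SD 0.5 on L\* only — luminance dominates the texture of real
skin, and keeping a\*/b\* smooth makes planted ΔE controllable. Objects
are constant Lab offsets with CIE76 magnitude equal to the requested ΔE:

* **wrinkles** — constant-width strokes along circular-arc paths
  (arc length = nominal length; stadium formula for nominal area;
  contrast is a pure L\* depression);
* **spots/pores** — ellipses (axis ratio from the requested eccentricity)
  whose polar radius carries a sinusoidal modulation
  r(θ) = r₀(1 + a·cos kθ); the amplitude is solved numerically so the
  continuous curve's perimeter²/area equals a requested nominal
  circularity. Spots default to 5 lobes and pores to 3, both at nominal
  circularity 27 — low lobe counts digitise faithfully at pore radii
  (~9 px), keeping measured circularity comfortably above the 20 floor;
* **texture** — small smooth ellipses (circularity ≈ 4π).

Default parameter ranges keep every nominal measurement at least 20% away
from every classification threshold, so generated objects are unambiguous
class members: because the ±20% bands around the area thresholds 3, 4 and
5 mm² jointly cover 2.4–6 mm², wrinkles default to ~6.6–7.4 mm²
(13 × 0.5 mm strokes) and pores/texture to ≤ 2.4 mm². The idealised
thin-stroke perimeter/length ratio is 2.0 — exactly 20% below the 2.5
cutoff and the attainable extreme, since P/L > 2 for any finite-width
stroke. In isolated mode, placement is rejection sampling with a
1000-attempt cap and a 20 px minimum clearance (never below the 2 px the
disjointness contract promises); failure raises an error carrying the
number of objects placed. Identical spec + seed gives bit-identical
images and ground truth.

What the generator does **not** emulate: photorealistic skin texture
(pigment mottle, specular highlights, hair), perspective and lens
distortion, illumination gradients, chromatic noise, overlapping or
low-contrast objects near the rule boundaries, and inter-visit
registration error. Passing the round-trip tests therefore demonstrates
that the measurement chain is correct and self-consistent — not that the
printed rules would reach any particular accuracy on clinical
photographs.

### Cohort

Per subject *i*, two standard-normal latents: aging severity sᵢ and
treatment response fᵢ. For each parameter p with calibration
(μ₉₉, σ₉₉, μ₀, σ₀) (defaults: the measured 86-subject table — hydration
56.71 ± 7.11 → 47.76 ± 8.68, TEWL 12.34 ± 3.83 → 13.36 ± 3.18, wrinkles
0.20 ± 0.18 → 0.37 ± 0.28, etc.):

* baseline and pre-treatment values are jointly Gaussian with the stated
  means/SDs and a test–retest correlation ρ_b (default 0.7, a plausible
  decade-scale stability for adult skin phenotypes), with the
  pre-treatment innovation loaded on sᵢ (loading g = 0.6, signed by the
  parameter's aging direction), so all parameters deteriorate together;
* treatment visits interpolate back toward the subject's own baseline:
  v(t) = v₀ + ρ(t)(v₉₉ − v₀) + scale(t)(β_p fᵢ + w_p ε), with recovery
  fractions ρ(t) defaulting to (0.43, 0.64, 0.84) at 2/8/12 months —
  fractions of the decade's deterioration recovered, mirroring the
  reported reversal trajectory (≈ −4.7, −7.0, −9.2 of −11 years);
* the response loadings β_p for TEWL/wrinkles/spots/roughness are solved
  in closed form (a quadratic per parameter) so that the **population**
  Pearson r between Δhydration(12M−0M) and each Δoutcome(12M−0M) equals
  the requested target (default **−0.32**) exactly — the proportional
  reversion term already induces part of that negative correlation, and
  the shared factor supplies (or cancels) the remainder. Unachievable
  targets are rejected with the offending parameter named. Outcome noise
  w_p defaults to 0.2 × SD of the subject's decade change; hydration's
  response variance is (0.3 × SD)² with 90% of its SD on the shared
  factor.

Everything is a linear map of i.i.d. Gaussians, so the implied joint is
always a valid distribution; means/SDs at the two anchor visits are exact
by construction (sample means land within 3·SD/√86 of target in ≳ 99% of
seeds). Gaussianity means a parameter with SD comparable to its mean
(sebum: 36.7 ± 29.9) occasionally goes negative; values are left
untruncated to keep the moments exact.

## Problem sizes and numerics

The validation suite runs 200 synthetic images (256 × 256 px, one object
per class) for the classification round-trip, 200 cohort seeds for
calibration, n = 5000 for correlation recovery and ≥ 500 replicates for
null p-value uniformity; these sizes put Monte-Carlo standard errors well
inside the asserted tolerances (SE(r) ≈ 0.013 at n = 5000). Boundary
thresholds are compared inclusively and exactly (no epsilon); min–max
scaling errors out on constant parameters, naming the parameter; the
reversal denominator epsilon is 10⁻⁶ in score units.

## Known limitations

* The segmentation operator is a stand-in: only the downstream selection
  rules are fixed by the method; background subtraction + thresholding is
  the simplest operator consistent with them and is isolated behind
  `SegmentationParams`.
* Whether wrinkle "length" means skeleton arc length or maximum caliper
  length is ambiguous in the rule as printed; arc length is used because
  it keeps perimeter/length ≈ 2 for curved strokes.
* The pixel scale of the original capture system is not public;
  0.1 mm/px is an assumption, and all mm thresholds scale through it.
* Correlation calibration targets a single shared-factor structure; it
  reproduces pairwise hydration–outcome correlations exactly but does not
  attempt to match the full outcome–outcome correlation matrix of any
  real cohort.
* Reported p-values in small clinical tables are not reproduced and not
  targeted; the statistical layer reports its own n alongside every test.
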
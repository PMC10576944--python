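# Methods

## Pixel classification

Each pixel is mapped to hue/saturation/intensity with the hexagonal HSV
hue scaled to [0, 1) (achromatic pixels get hue 0), saturation
(max − min)/max (0 for black), and intensity the unweighted channel mean
(R + G + B)/3 — the unweighted mean, not luma, because that is the
convention of the positive-pixel algorithm family this re-implements.
The rule order is: (1) exclude bright unsaturated pixels as bare glass;
(2) gate positive candidates by circular hue distance to the DAB-brown
center and a saturation floor; (3) bin candidates by intensity into
strong/medium/weak; (4) everything else, including candidates brighter
than the weak bin, is negative. Hue distance is circular
(min(|Δ|, 1 − |Δ|)) because hue is periodic.

Default thresholds (all overridable from the `classifier:` section of a
YAML config):

| parameter | default | meaning |
|---|---|---|
| hue_center | 0.10 | DAB brown on the unit color wheel |
| hue_width | 0.50 | full width of the positive hue window |
| saturation_min | 0.04 | candidate floor; also the glass gate |
| i_strong_upper | 100 | strong bin: I ≤ 100 |
| i_weak_lower | 175 | medium bin: (100, 175] |
| i_weak_upper | 220 | weak bin: (175, 220] |
| background_intensity_min | 230 | glass exclusion intensity |

These are the published defaults of the vendor positive-pixel-count
algorithm family; the automatic glass filter supplements the manual-ROI
workflow so that fraction denominators stay meaningful on images whose
annotations do not tightly hug the tissue.

## Regions of interest

Annotations are GeoJSON polygon sets in pixel coordinates (0-based, x
rightward, y downward) with a `role` of include or exclude, or binary
mask PNGs. A pixel is in-analysis iff its center (x + 0.5, y + 0.5)
lies inside the union of include polygons and outside the union of
exclude polygons; exclude wins on overlap. Containment is delegated to
shapely; a center lying exactly on a polygon edge counts as outside,
which is the one fixed convention (test fixtures avoid edges through
pixel centers, where distinct correct implementations disagree at the
last floating-point bit). A missing ROI means the whole image is
analyzed, relying on the glass filter — this is what lets synthetic
cores be scored without annotations.

## Scoring

Class fractions use the analyzed (non-excluded) pixel count as the
denominator; pixels proxy for cells, as in any pixel-counting scorer.
The H-score is 1·f_weak + 2·f_medium + 3·f_strong with fractions on the
[0, 1] scale, so H ∈ [0, 3] (the 0–300 convention is the same number
times 100; group means such as 0.95 only make sense on the 0–3 scale).
Samples with no analyzable pixels raise an explicit unscorable error
and are dropped from cohort statistics with a logged warning.

## Cohort statistics

The headline grouping dichotomizes melanoma T stage by Breslow
thickness: thin = {T1, T2} (≤ 2.0 mm) versus thick = {T3, T4}
(> 2.0 mm); arbitrary {label: [stages]} rules are supported. Groups are
summarized by mean and SEM (sample sd with n − 1 over √n). The default
test is the classical pooled-variance Student t (the minimal reading of
"unpaired t-test"), with Welch–Satterthwaite available by flag to
document the ambiguity; p is the two-sided tail probability of the t
distribution and significance uses p ≤ α with α = 0.05. Degenerate
inputs follow explicit conventions: two identical constant groups give
t = 0, p = 1; zero variance with unequal means gives p = 0; both warn.
Fold change is reference-group mean over comparison-group mean with
thin as the reference, so a ratio above 1 reads as an "x-fold decrease"
in thick tumors; it is reported at full precision (0.95/0.57 = 1.667,
conventionally rounded to 1.6-fold). Single planned comparisons carry
no multiplicity adjustment; when several comparisons are reported
together the CSV adds a Bonferroni-adjusted column for transparency.

## Synthetic data generator

Rendering follows Beer–Lambert mixing: channel transmittance
255·10^(−OD) with OD the concentration-weighted sum of the hematoxylin
(0.65, 0.70, 0.29) and DAB (0.27, 0.57, 0.78) optical-density vectors —
the standard literature deconvolution values. Tissue is a union of
random ellipses on a white background (morphological realism is a
non-goal; ellipses make area fractions controllable). DAB-positive
area is carved from the tissue by ranking tissue pixels on a
Gaussian-smoothed random field and taking exact pixel counts per grade,
which yields contiguous blobs whose realized fractions match the
targets to single-pixel rounding. Each grade is rendered as pure DAB at
the concentration calibrated (by bisection on the strictly decreasing
intensity-versus-concentration curve, tolerance 0.5 intensity units) to
the midpoint of its intensity bin; tissue-negative pixels carry
hematoxylin at the counterstain density (default 0.6). Rendering DAB
pixels without counterstain underneath is a deliberate simplification:
it makes noise-free classification recover the ground-truth labels
exactly, so recovery tests isolate the effect of noise. Gaussian camera
noise (default sd 2, in 8-bit units) is added after rendering and
clipped to [0, 255]; ground-truth labels are assigned pre-noise.
Ground-truth fractions use tissue pixels as the denominator, matching
the ROI logic of the real pipeline.

Cohort simulation draws each sample's (weak, medium, strong) fractions
from a Gaussian around the group mean and clips to the valid simplex.
The study-design preset uses thin means (0.35, 0.15, 0.10) and thick
means (0.25, 0.10, 0.04), whose grade-weighted sums are H = 0.95 and
0.57. The between-sample spread is not identifiable from group means
and SEMs alone, so it is a free parameter; the default sd of 0.06 per
class fraction (≈ 0.22 on the H scale) reflects tight within-group
error bars while leaving clearly visible between-sample variation.
Clipping at the simplex boundary slightly raises the realized thick
mean (≈ +0.02 on H) because its small strong fraction truncates at
zero; this is an accepted property of the clipped-Gaussian design.

What the generator does not emulate: nuclear and cellular morphology,
stain co-localization within a pixel, scanner color calibration,
uneven illumination, and section artifacts. Passing recovery tests
therefore demonstrates correctness of the pipeline arithmetic and its
robustness to additive noise — not classifier validity on real tissue,
where thresholds must be checked against stained controls.

## Numerical choices and problem sizes

Calibration bisects to within 0.5 intensity units of the bin midpoint
and verifies the rendered pixel's class, raising a calibration error if
a gate makes the bin unreachable. Classifier parameters are validated
at use (not construction) so invalid settings surface where they are
consumed. Simulated acceptance checks use 64–96 pixel frames and
replicate counts (20 cohort replicates; 50 recovery cores; 10,000 null
and 1,000 power simulations) chosen so the whole suite runs in a couple
of minutes on one CPU while keeping Monte Carlo error well inside the
margins being tested; the statistical calibration checks draw H-scores
directly from the group model rather than rendering images, since the
t-test consumes only per-sample scores.

## Known limitations

- Numeric agreement with any particular vendor build of the
  positive-pixel algorithm cannot be verified, as vendor thresholds and
  versions vary; the defaults are the published ones and everything is
  configurable.
- H-scores treat cores as independent units; multiple cores per patient
  are not pooled or weighted.
- The normal-skin preset (broad weak staining, no strong component)
  models only the faint diffuse appearance of normal epidermis;
  normal-versus-tumor statistics are intentionally not implemented.
- Boundary pixels whose centers fall exactly on annotation edges follow
  the documented outside convention rather than any vendor-specific
  tie-break.
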
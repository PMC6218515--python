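# Methods

This note records the models and procedures implemented in `mitoflow`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions adopted where the design was open.

## Conventions

Images are row-major with 0-based indices; `(row 0, col 0)` is top-left.
Motion vectors use a mathematical frame: x̂ points along +columns, ŷ points
*up* (the row gradient is negated), angles are `atan2(v, u)` in (−180°,
180°], and the angle of a zero vector is defined as 0. Stacks are `(T, H,
W)` arrays of 8- or 16-bit intensities; label masks are integer arrays with
background 0 and labels contiguous `1..n` per frame. Missing TIFF physical
metadata defaults to 1 µm/pixel and 1 s/frame with a logged warning — every
analysis here is unit-agnostic except display.

## Segmentation

The workflow is histogram matching (optional, against a reference video's
pooled histogram; a monotone per-frame intensity remap), optional white
top-hat with a disc element (removes slowly varying background), Otsu
thresholding, removal of objects below `min_object_area` (default 5 px),
8-connected labelling, and optional watershed declumping.

Two threshold modes exist because they serve different stages: a single
global Otsu threshold for morphology work, and an adaptive mode for the
motion ROI. Adaptive mode computes Otsu per tile (default side 65 px) at
50 % overlap, assigns near-constant tiles the global threshold, and
bilinearly interpolates the tile-centre thresholds to a full-resolution
threshold surface, which avoids seam artifacts. 8-connectivity was chosen
so thin diagonal tubules of networked mitochondria do not fragment; the
Otsu tie-break (lowest threshold among the argmax set, as implemented by
scikit-image) favours larger foreground for dim organelles.

Declumping seeds a watershed at regional intensity maxima surviving
h-maxima suppression; the default depth is 5 % of the frame's dynamic
range, which suppresses seeds arising from noise maxima. Flooding runs on
the inverted intensity restricted to the foreground, with 1-px separating
boundaries; any foreground component left seedless keeps its full extent,
so declumping never reduces the object count. Foreground is conserved up to
the boundary pixels.

Segmentation accuracy is scored as foreground Jaccard × 100 per frame plus
a per-object IoU table (each ground-truth object matched to its best
overlapping automatic object); two empty masks score 100.

## Feature schema

22 named slots: morphology 1–11 and 22 (area, perimeter, major/minor axis
from the second-moment ellipse, eccentricity, solidity, extent, form factor
4πA/P², max/median radius from the interior Euclidean distance transform,
aspect ratio, convex area), intensity 12–14 (integrated, mean, SD over
object pixels), motion 15–18, texture 19–21. Perimeter is the
marching-squares contour length; it scales linearly under upscaling within
a discretisation tolerance that shrinks with object size (≈5 % for objects
≳20 px across). Degenerate digitisations are regularised: zero perimeter ⇒
form factor 1, the minor axis is floored at one inter-pixel distance for
the aspect ratio, and eccentricity is capped just below 1.

The motion slots summarise frame pairs at the video scale and are this
package's own reconstruction (their identities are not externally fixed):

* **15/16** — mean/SD over frame pairs of the ROI-mean per-pixel vector
  magnitude ("motion activity"). The summed resultant was deliberately not
  used here: vectors of independently moving structures cancel, so the
  resultant is nearly blind to the *amount* of motion (measured
  stressed/control ratio ≈1.0 for the resultant vs ≈1.35 for activity at
  doubled jitter).
* **17** — mean absolute radial component per ROI pixel about the reference
  point (frame centre unless given).
* **18** — magnitude of the net resultant summed over all pairs
  (directional persistence).

## Motion estimation

The intensity-flow estimator is described in the README. Numerical
choices: gradients are central differences with one-sided stencils at
borders (the minimal unbiased, oracle-testable choice); the rescale
constant generalises to (D+G)/2G by bit depth so 16-bit input does not
clip; magnitudes are sums of dimensionless rescaled-intensity gradients
with no physical calibration.

Two properties of the estimator are worth knowing. First, the summed
resultant over the ROI is mathematically a boundary flux of D′ across the
ROI contour: it recovers the motion *direction* well, but its magnitude
saturates once the displacement exceeds the gradient stencil (measured
20-seed means for a translating dot at 0/1/2/4 px: 0, 5.2, 6.2, 6.1). It
is a direction estimator more than a speed estimator; per-pixel motion
activity is strictly monotone in displacement over the same range and is
what the video features use. Second, shapes with long flat edges bias the
summed direction towards the axis normals when the displacement is small
relative to the edge (up to ≈20° for an axis-aligned rectangle moved 2 px
at 30°; exact on-axis; ≤5° by 4 px). Discs show errors below ≈6° at all
tested displacements.

The Lucas–Kanade baseline is a classic structure-tensor least-squares
solve per pixel (default 15-px window); pixels whose tensor condition
number exceeds 10⁴ contribute zero. Its flow is in pixels/frame, so
magnitude comparisons between the two estimators are made per estimator
against its own output on the non-fading version of a scene:
`magnitude_acc = 100·max(0, 1 − |M_est − M_ref|/M_ref)`. Angle accuracy is
`100·(1 − |wrapped error|/180)` and is undefined (reported missing) for
zero-displacement ground truth.

Directional analysis projects each pixel vector onto the unit radial
vector from a reference point (e.g. the nucleus); positive = away. A pixel
coinciding with the reference contributes 0. Per-class analysis reports
both the raw per-object magnitude mean and an area-normalised mean, since
classes differ greatly in total area and either normalisation can be
wanted.

## Texture

**Fractal dimension (differential box counting).** For box size *r* the
window (default 33 px, square) is partitioned into an *M*×*M* grid of
*r*×*r* columns with *M* = ⌊W/r⌋ (the remainder strip is cropped); each
column spans `ceil(max/h) − ceil(min/h) + 1` grey-level boxes of height
*h* = *r·G/W*. The dimension is the least-squares slope of log N(r)
against log M(r); regressing on the realised grid side rather than log(1/r)
makes a flat surface come out at exactly 2 even when *r* does not divide
the window, at the cost of a slightly different abscissa when it does not.
Results are clamped to the admissible surface range [2, 3]. Default box
sizes {2, 3, 4, 6, 8, 12, 16}.

**Lacunarity (gliding box).** An *r*×*r* box slides over every position of
the binary segmentation; with box mass = foreground count,
Λ(r) = var/mean² + 1 (population variance), and the reported feature is
the mean of Λ over the box sizes that fit. Lacunarity is computed on the
segmentation mask, not raw intensity, because it measures gaps in the
mitochondrial pattern. Cell-scale texture evaluates the fractal dimension
on windows centred on a stride-16 lattice inside the cell mask (mean and
population SD reported) and lacunarity within the cell's bounding box.

## Classification

Morphology (per-object) and health (per-video) classification share four
algorithms: KNN (default k = 5), Gaussian naive Bayes, linear discriminant
analysis with pooled covariance, and an error-correcting output-code
classifier realised as one-vs-one linear discriminants with vote (Hamming)
decoding — the minimal complete code for 2–3 classes. Features are
z-scored by training statistics for KNN/LDA/ECOC; naive Bayes is
scale-equivariant and left unscaled. Ties (KNN votes, equal posteriors)
resolve to the smallest class index in sorted label order, so predictions
are deterministic. Singular pooled covariances are handled by the SVD
formulation of the discriminant solve. Models serialise to JSON as
spec + training records and are retrained deterministically on load.

Evaluation protocols: a single train/test split disjoint by provenance for
morphology validation; stratified 5-fold cross-validation (shuffled from
the spec seed) for health classification. Class area fractions divide each
class's summed object area by the cell's total mitochondrial area and
always sum to 1. The exhaustive feature-subset search enumerates every
subset up to a size cap (guarded by an evaluation budget), scores each
with the chosen protocol, and sorts by accuracy, then subset size, then
lexicographic order — fully deterministic.

## Synthetic data

Every generator is a pure function of its parameters and seed.

**Motion scenes** render an analytic shape (dot r=8, disc r=16, rectangle
40×24, peak 200 on 8-bit) with fractional edge coverage, so sub-pixel
translations are realised by re-drawing, not resampling; "uneven" cases
carry a fixed linear ramp from 40 % to 100 % of peak across the object
along +x; "fading" cases scale frame two by 0.5. Scenes are noiseless by
default (optional Gaussian read noise).

**Morphology fields** place non-overlapping objects by rejection sampling
(≤1000 attempts, 2-px clearance): punctate = discs of area ~10–40 px;
networked = dilated momentum-random-walk skeletons with up to two branches
(elongated, low solidity); swollen = ellipses of area ~200–800 px with
smooth sinusoidal internal heterogeneity (so their per-object intensity SD
is the highest of the three classes, a property the feature tests check).
Noise is Poisson on the expected intensity plus Gaussian read noise
(default σ = 2 grey levels) — low enough that ground truth dominates.

**Morphogenesis videos** realise a per-frame class-mix timeline on
persistent object slots whose positions jitter between frames; slots keep
their location but switch class as the mix changes (fragmentation or
swelling in place). Small annuli ("donuts") appear only here as
transitional shapes and carry the networked label, keeping the classifier
three-class.

**Condition pairs** generate networked-dominant videos whose object shapes
persist across frames; only positions jitter (sub-pixel, σ = 0.6 px
baseline). The stressed arm multiplies jitter by `motion_scale` (default
2.0), ramps global brightness to `intensity_drift` × initial by the last
frame (default 0.93), and pulls objects towards cluster attractors by
`texture_clumping` (default 1.3). The drift and clumping defaults were
chosen so that each channel alone is a weak classifier and the conditions
are separated reliably only in combination, which is the regime the health
classifier exists for; passing an explicit `stress_params` dict sets the
unnamed factors to 1 so a single channel can be isolated.

What the generators do *not* emulate: point-spread blurring and optics,
photobleaching kinetics, 3-D structure, cell boundaries and crowding,
camera fixed-pattern noise, or genuinely directed transport along
cytoskeletal tracks. Tests passing on these fixtures therefore demonstrate
the correctness of the measurement code and the recoverability of planted
effects — not performance on real microscopy, which depends on
acquisition quality and training libraries.

## Problem sizes

The shipped validation suite and tests use desk-scale problems chosen as
the smallest sizes at which the planted effects are unambiguous: 128×128
scenes for motion validation; 256×256 fields with 24–30 objects for
segmentation and morphology classification (3 training fields, 10 test
seeds); 96×96 × 6-frame videos with 6–12 videos per arm for health
classification (10 effect seeds, 20 null seeds).

## Known limitations

* The summed-vector magnitude saturates with displacement (see above); use
  motion activity when the amount of motion matters.
* Flat-edged objects bias summed direction at sub-edge displacements.
* Adaptive thresholding assumes tiles with <5 % of the global dynamic
  range are background; structured backgrounds above that are segmented.
* The DBC abscissa uses the realised grid side; box sizes that divide the
  window side exactly reproduce the textbook regression.
* Health classification assumes per-video means are exchangeable within an
  arm; batch effects between acquisition sessions are not modelled.
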
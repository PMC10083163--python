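# Methods

## Problem and approach

Diabetic macular edema (DME) produces three kinds of retinal fluid visible
in OCT B-scans — cystoid macular edema (CME), diffuse retinal thickening
(DRT) and serous retinal detachment (SRD) — whose boundaries are often too
diffuse for a meaningful segmentation, particularly for DRT. `octfluid`
implements the *diffuse* alternative: classify small windows of the retina
and aggregate their votes into per-pixel confidence maps instead of drawing
hard contours.

The pipeline is: (1) sample 64×64 windows from labeled B-scans, each window
labeled by its center pixel; (2) train a densely connected convolutional
patch classifier under one of three regimes; (3) slide 64×64 windows over
the retinal region of interest (ROI) with 60 px overlap, classify each, and
let every window vote on every pixel it covers — a pixel's confidence for a
class is the fraction of covering windows that voted for that class;
(4) profile the maps per connected component of the reference labeling.

## Training regimes

Expert annotation uses an "uncertainty" label for regions known to be
pathological without a confidently assignable fluid subtype. The three
regimes differ only in how they treat those windows:

* **baseline** — 4-class training (healthy/CME/DRT/SRD) from scratch;
  uncertainty windows are discarded.
* **generalist transfer** — start from a model pretrained on a generalist
  image domain, replace its classifier head with the four target classes
  (keeping all other weights bit-for-bit) and fine-tune like the baseline.
  Externally pretrained weights can be loaded from a checkpoint; when none
  are given, a synthetic pretext task (6-way classification of oriented
  gratings, blob fields and speckle) stands in as the generalist domain at
  desk scale. The model's provenance metadata records which source was used.
* **uncertainty transfer** — stage 1 trains a *binary* healthy-vs-pathological
  classifier in which the pathological class pools CME, DRT, SRD *and*
  uncertainty windows, so the body filters see the weakly labeled patterns;
  stage 2 replaces the head with the four subtype classes and fine-tunes on
  defined labels only.

Class imbalance is countered by per-sample loss weights: in the 4-class
problem a class is weighted by the summed support of the other three classes
over its own (so the healthy weight is (CME+DRT+SRD)/healthy); in the binary
problem healthy is weighted by (uncertainty+CME+DRT+SRD)/healthy and the
pooled class by the reciprocal. Validation loss uses the same weights so it
is comparable across regimes; the weighting is realized as loss weights
rather than a weighted sampler because it is deterministic and
batch-composition independent (a sampler would make the loss depend on the
draw).

## Training loop

* Optimizer AdamW (decoupled weight decay) with AMSGrad; lr₀ = 0.01, weight
  decay = 0.01, β = (0.9, 0.999), ε = 1e−8.
* Batch size 250 for the full backbone; the reduced desk-scale variant
  automatically drops to 64 (a 250-window batch of a tiny model wastes most
  of its gradient signal and memory at desk problem sizes).
* Horizontal flip augmentation with p = 0.5 (retinal patterns occur in both
  orientations).
* Reduce-on-plateau: lr ×0.66 after 10 consecutive epochs without
  validation-loss improvement; early stop after 25 (room for two reductions
  plus five epochs of margin); "improvement" means a drop of at least 1e−6,
  a tolerance the loop needs to be testable and that is far below any
  meaningful loss change.
* The returned model is the snapshot with the best validation loss.

## Backbone

The classifier is a densely connected network. The `densenet161` variant is
the full configuration — 7×7 stride-2 stem, 3×3 stride-2 max pool, blocks of
(6, 12, 36, 24) bottleneck layers with growth 48, bn_size 4 and
0.5-compression transitions (growth and compression are the standard
DenseNet-161 values), stage resolutions 32→16→8→4→2 on a 64 px input, batch
normalization and ReLU before every dense-block convolution and transition
and once more before the classifier, softmax head. Convolutions are
Kaiming-initialized, fully connected layers uniform on ±1/√fan_in.

The `reduced` variant is first-class, not a mock: identical wiring with a
5×5 stride-4 stem and two (2, 2) blocks of growth 12 (~14 k parameters), so
every regime runs end-to-end on one CPU in seconds. All regime logic is
variant-agnostic. Both variants run on a compact numpy engine
(`octfluid.nn`) with explicit forward/backward passes (im2col convolution,
batch-norm, dense-block concatenation, AdamW+AMSGrad); its gradients are
verified against central finite differences in the test suite. The engine
is single-precision: bit-deterministic for a fixed seed, with half the
memory traffic of double precision.

## Confidence maps

Windows are laid on a regular `stride = window − overlap` lattice (64 px
windows, 60 px overlap → stride 4) anchored at the ROI bounding-box
top-left; trailing rows/columns are appended when the lattice would leave
the far ROI edge uncovered, which may break uniform stride once per axis —
full coverage is required because coverage is the voting denominator.
Windows are kept if they intersect the ROI at all; votes land only on ROI
pixels; window contents reaching past the image border are completed by
mirror reflection (border pixel not duplicated). Votes are hard argmax
labels, because the map's confidence is *defined* as a proportion of
labeled windows, not an average of soft scores. Image-anchored tiling is
available as an option (`anchor="image"`).

An interior pixel under the default geometry is covered by 16×16 = 256
windows, so confidence is resolved in steps of 1/256. Rendering maps
confidence through a piecewise-linear cold-to-warm palette
(blue→cyan→green→yellow→red) whose central stops are compressed so
mid-range differences get steep color gradients; non-ROI pixels show the
underlying grayscale.

## Map analysis

For each 4-connected component of a class in the reference mask, the
analysis records (component size, maximum map confidence inside it). The
scatter is summarized by a sliding median over size windows of 1000 px
advanced in steps of 10 (closed-open intervals; empty windows skipped;
support abscissa at the window midpoint), smoothed by a cubic b-spline
through 10 evenly spaced support points. 4-connectivity is the conservative
choice and is stated so tests can be exact; when fewer support points exist
than the spline degree needs, the raw medians are returned with a flag
rather than an extrapolated curve.

Sliding windows move over size *values*, not sorted ranks — the trend is a
function of physical component size.

## Metrics

Per-class one-vs-rest accuracy, precision, recall, F1 and Matthews
correlation from argmax predictions (ties broken toward the lowest class
index), plus AUC in its Mann–Whitney–Wilcoxon form (ties count ½, computed
via midranks, exact at any size). Degenerate denominators yield "undefined"
rather than silent zeros; aggregate rows opt into the undefined-as-zero
convention explicitly. The overall row is the class-support-weighted mean
of the per-class values (an unweighted mean is available); uncertainty
windows never enter the metrics, since they carry no reference subtype.

## Synthetic phantoms

The phantom generator produces the statistical structure the pipeline
assumes, not photorealistic OCT: a retinal band between two smooth random
cubic curves (ILM-like above, RPE-like below), layered internal
reflectivity, per-class Gaussian texture under multiplicative speckle, and
planted regions per class morphology — hyporeflective elliptical pockets
(CME), speckled irregular patches with thresholded-noise borders (DRT), and
domes resting on the RPE floor (SRD). Uncertainty is synthesized where it
arises in expert labeling: halos of configurable width (default 3 px,
4-connected dilation) around every planted region, plus optional
free-standing diffuse patches. Default geometry is 256×384 px, 8-bit
(16-bit behind a flag); per-type planting probabilities default to
CME 0.7 / DRT 0.6 / SRD 0.45 / standalone-uncertainty 0.35 — free
parameters (no per-image prevalence is documented for clinical graded
datasets at this granularity) chosen once so a modest dataset contains all
classes while healthy tissue dominates.

`PhantomConfig.high_contrast()` is the controlled-contrast preset used by
the learning sanity checks: every fluid type planted in every image, class
mean gaps of several noise standard deviations. What passing tests on
phantoms shows is that the *pipeline machinery* — sampling, weighting,
regimes, transfer plumbing, voting, analysis — behaves as specified; it
does not show clinical-grade discrimination, because real OCT texture is
far less separable than a mean-offset Gaussian model, speckle is
spatially correlated, and device differences (Cirrus vs Spectralis) are not
modeled.

## Problem sizes and numerical choices

Desk-scale defaults: 12–24 phantoms, 6 folds, 16–25 samples per label per
image, the reduced backbone, ≤30 epochs; the full profile mirrors the
356-image / 60-split / DenseNet-161 configuration and is intended for
serious hardware. The learning sanity checks use 12 phantoms × 16 samples
per label over 5 seeds. Window coordinates are 0-based (row, col); an even
window of side w centered at c spans [c − w/2, c + w/2) per axis. Sampling
of window centers is without replacement (with replacement would duplicate
patches); labels with fewer candidates than requested contribute all of
them rather than dropping the image, which would bias class balance. Fold
assignment is uniformly random at image level without stratification —
cross-validation over all fold combinations absorbs residual imbalance.

## Known limitations

* The numpy engine is CPU-bound; the full DenseNet-161 variant is provided
  for fidelity of shape and initialization, not for full-scale training.
* Phantoms do not model device-specific noise, vessel shadows, or motion
  artifacts; transfer-regime *advantages* (as opposed to contracts) are
  therefore only weakly exercised.
* The generalist pretext task is a desk-scale stand-in; conclusions about
  generalist-domain transfer require real pretrained weights, which the
  interface accepts as checkpoints.
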
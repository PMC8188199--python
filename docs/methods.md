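# Methods

## Scope and model

imgtrain trains softmax image classifiers — small CNNs and MLPs — under a
class-weighted cross-entropy loss with SGD plus classical momentum. The
package's substance is the *workflow* around the optimizer: uniform dataset
containers, a fixed augmentation chain, per-epoch balanced sampling,
epoch-granular live hyper-parameter control, best-checkpoint selection by
validation accuracy, complete provenance, and the tile-based
segmentation-as-classification pipeline. The network layer engine
(`imgtrain.nn`) is a compact seeded NumPy implementation: stride-1
convolutions via sliding windows, 2×2 max pooling, ReLU, inverted dropout,
dense layers, identity residual wrappers, and per-layer freeze flags.
Exact gradients were verified against float64 central differences during
development, and a checkpoint carries weights plus optimizer state so an
interrupted run resumes identically.

## Dataset container and preprocessing

An `ImageSet` is an (N, H, W, C) uint8 array, C ∈ {1, 3}, with integer
labels, class names, per-image source ids, and a split tag. Folder trees
(one subdirectory per class; PNG/TIFF/JPEG) and an HDF5 layout
(`images`, `labels`, `source_ids`, attrs `class_names`/`split`) are read
and written; `HDF5ImageSet` presents the same contract while streaming
batches from disk for datasets larger than memory.

Conversions and their conventions:

* **RGB → gray** uses the luminosity weights (0.21, 0.72, 0.07), which sum
  to one and reflect the eye's sensitivity to green. Output is
  round-half-up, clipped to [0, 255]; because the weights are exact
  decimals the rounding is done in integer arithmetic,
  ⌊(21R + 72G + 7B + 50)/100⌋, so results carry no float-tie ambiguity.
  Gray → RGB stacks three identical channels, making the round trip the
  identity.
* **Rescaling** by factor f maps a side to ⌊side·f⌋ (so 28 px at f = 1.15
  becomes 32 px) with nearest, linear, quadratic, or cubic interpolation.
* **Size equalization** center-crops or zero-pads to a square target;
  odd remainders go to the trailing (bottom/right) side. Rectangular inputs
  are handled per axis. Coordinates are row-major, origin top-left,
  0-based, half-open.
* **Normalization**: divide-by-255; dataset standardization with the
  population mean/SD of the *training* images only; or per-image
  standardization (a constant image gets SD 1, mapping to all zeros, to
  avoid division by zero). Fitted statistics never read validation or test
  pixels.

## Augmentation

Operator order is fixed: flips → rotation → shift → zoom → additive
brightness → multiplicative brightness → Gaussian noise → one clip to
[0, 255] → center crop to the target side. The final crop comes after the
geometric operators so their edge artifacts fall into the cropped margin.
Parameters (all uniform draws): flip coin per enabled axis; rotation angle
in ±rotation_max degrees; integer shift in ±shift_max pixels per axis;
zoom factor in [1−δ, 1+δ] (the "±δ" zoom reading); brightness offset in
±brightness_add_max and multiplier in [lo, hi], both applied to raw
intensities before normalization; per-image noise SD uniform in
[0, noise_scale_max], then i.i.d. zero-mean Gaussian per pixel. Geometric
resampling is nearest-neighbor (keeps the 8-bit value set; vacated pixels
are 0); exact multiples of 90° on square frames take a lossless grid
rotation. Clipping happens once, after the noise stage. Each image draws
from a stream seeded by (config seed, batch index), so a batch is
bit-reproducible in any process. Two presets reproduce documented
benchmark settings (`cifar_gray`, `fashion_mnist`).

## Architectures

Registered builders generate a network for any compatible input side,
channel count, and class count (incompatible sides raise an error naming
the minimal side):

| name | structure |
|---|---|
| `lenet5` | conv 6@5×5 → pool → conv 16@5×5 → pool → dense 120/84/K |
| `nitta_6layer` | conv 32/32 → pool → conv 64/64 (3×3 'same') → pool → dense 256/K |
| `residual_10layer` | three blocks (32, 64, 128 filters) of conv → [conv + identity skip] → pool, then dense 256/128/64/K |
| `mlp_64_32`, `mlp_256_128` | flatten → dense hidden layers → K |

Filter counts and dense widths follow the architectures' canonical
published forms where a name pins them (LeNet-5) and otherwise are fixed
documented choices recorded in the `ModelSpec`, so tests can pin exact
parameter counts. Dropout layers sit after hidden dense layers; the rate
is a run-time hyper-parameter. Weights are He-normal from a seed. The
registry is a plug-in dict: `register_architecture` makes any user builder
constructible by name.

**Freezing and transfer.** Every parameterized layer has a trainable flag;
frozen layers receive no updates (their weights stay bit-identical) while
gradients still flow through them. `plateau_unfreeze` mechanizes gradual
unfreezing: when the best validation accuracy of the last `patience`
epochs improves on the best of all earlier epochs by less than `epsilon`,
the deepest still-frozen layer (closest to the output) is released. The
defaults (patience 5, epsilon 0.005) are conventional choices — plateau
detection has no canonical constants — and both are explicit parameters.

## Training loop

Per epoch: draw the training order (a balanced per-class sample of
n_per_class indices — sampling with replacement only for classes smaller
than n_per_class — or a full shuffle when n_per_class is unset); augment
each mini-batch; normalize; forward/backward; SGD step. After the epoch,
accuracy on the full un-augmented validation set is computed, and the
best-so-far weights are retained; training ends with the best weights in
the model. History records one entry per epoch: training accuracy over
that epoch's batches, validation accuracy, and a full snapshot of every
hyper-parameter in force.

**Live control.** Before each epoch the control source is polled: either a
flat YAML mapping (re-read every epoch, so file edits land at the next
epoch boundary) or a scripted schedule `{epoch: {key: value}}` (YAML or
in-memory dict). Adjustable keys: learning_rate, dropout_rate,
n_per_class, class_weights, batch_size, and every augmentation field.
Changes are applied for that epoch and logged as change events; an
unparseable control file warns and keeps previous values. Polling at epoch
granularity (rather than mid-epoch) is what makes runs with live
adjustments deterministic and replayable.

**Provenance.** The meta-file (`<run>_meta.yaml`) stores software version,
seed, the full initial configuration, the model spec with trainable mask,
SHA-256 content fingerprints of the train/validation sets, per-epoch
snapshots, change events, and the best epoch. `replay_from_meta` verifies
the fingerprints, rebuilds the model and schedule, and reruns — the
reproduced history is bit-identical because all randomness (weight init,
sampling, dropout, augmentation) derives from the recorded seed.

**Defaults.** Batch size 32, learning rate 0.01, momentum 0.9, dropout 0.
These are ordinary small-CNN settings, documented here as the package's
own choices; no claim is made that any benchmark was trained with them.
Loss is class-weighted cross-entropy — the natural pairing for a softmax
classifier with per-class loss coefficients.

## Evaluation

`evaluate` produces the confusion matrix (rows true, columns predicted;
predicted class = argmax probability), per-class precision/recall/F1 and
support (scikit-learn, zero-division reported as 0 with the affected
classes flagged), accuracy = trace/N, and one-vs-rest ROC and
precision-recall curves with points at every distinct predicted
probability (positive when p ≥ threshold) and trapezoidal AUCs. For binary
tasks the positive-class column of the per-class arrays is the single AUC
of interest. `confusion_cell_examples` returns the source ids behind any
confusion cell. `mean_sd` uses the sample (n−1) standard deviation and
reports SD as unavailable for a single value.

`threshold_purity` quantifies sorting-style decisions: among events with
p(positive) strictly above `upper`, the fraction truly positive; strictly
below `lower`, the fraction truly negative; events in [lower, upper] stay
unassigned. Strict inequalities are used, and an empty stratum is reported
as undefined (`None`), never as 0.

## Tile pipeline

Mask-labeled images (expert marks encoded as pure green RGB (0, 255, 0) in
an overlay image, or boolean masks directly) are cut into disjoint s × s
tiles in row-major order; residual borders are discarded with a warning. A
tile is class 1 ("with differentiation") iff it holds ≥ `min_marked`
(default 5) marked pixels. Because grid tiles are dominated by class 0,
extra positive tiles are drawn at uniformly random fully-inside offsets by
rejection sampling (accept at > min_marked − 1 marked pixels, budget 1000
attempts per tile, shortfall returned with a warning) — by default enough
to balance the class counts. Tile provenance (`source:rROW:cCOL`) survives
into the trained dataset. Prediction reconstructs the R × C class grid
plus per-tile probabilities; per-image accuracy is the fraction of
agreeing cells against the ground-truth grid, summarized as mean ± SD over
images. Masks are never normalized; tiles inherit the standard image
normalization. `TilePipeline` defaults (LeNet-5, 15 epochs, learning rate
0.01) were selected on synthetic fixtures as a configuration that
converges reliably on CPU in under a minute.

## Synthetic data

The generators are first-class, seeded, pure functions of their arguments;
they define the conditions under which the test suite demonstrates the
workflow.

* **Shapes** (`make_shapes_dataset`): up to six families (disk, square,
  cross, ring, bar, triangle) centered with small position jitter
  (±side/16), size U(0.28, 0.33)·side, foreground intensity U(180, 255) on
  a dim noisy background. The jitter is deliberately mild so the classes
  are separable even by a nearest-centroid baseline on raw pixels — the
  generator's job is to make CNN learning checks meaningful, not to model
  any real imagery.
* **Stained cultures** (`make_stained_culture`): 320 × 320 RGB images,
  warm background whose brightness (tint U(0.7, 1.25)) and per-channel
  cast vary per image, with reddish rotated-ellipse blobs (the stain) whose
  pixels define the exact ground-truth mask. This emulates culture
  photographs that vary in brightness, color, and stain distribution; it
  does not model cell morphology, focus gradients, or stain texture, so
  passing tile-pipeline tests demonstrate the pipeline's mechanics and
  learnability, not clinical-grade segmentation.
* **Cell events** (`make_cell_events`): single-cell crops in the style of
  imaging flow cytometry regions of interest. Each event is one centered
  disk with pixel area ~ N(area_mean, area_sd) and interior brightness
  ~ N(brightness_mean, brightness_sd); populations are Gaussian in the
  (area, brightness) feature plane — the simplest structure that makes
  rectangular gating and classifier training testable. Disk radii are
  fitted so the rasterized pixel count matches the drawn area to within a
  few pixels. Populations whose ±1 SD boxes overlap on both features
  trigger a warning since gates would mislabel. Real event images differ
  in texture, halo, and deformation; none of that is modeled.

Feature extraction follows the cytometry convention: area = number of
cell-mask pixels, brightness = mean grayscale over exactly those pixels.
Gates are half-open rectangles in (area, brightness).

## Numerical choices and degenerate inputs

* Round-half-up for the luminosity conversion (exact integer arithmetic);
  resized/augmented integer images are rounded then clipped once.
* Pad and fill value is 0 everywhere (equalization, rotation, shift, zoom).
* Augmentation draws happen only for enabled operators, in fixed operator
  order, so disabling an operator does not shift other operators' streams.
* A constant image under per-image standardization maps to all zeros.
* Empty strata in threshold purity, missing SD for n = 1, and zero-division
  metric cells are reported as undefined/flagged rather than silently 0.
* Size equalization is idempotent for crop and pad modes;
  `scale_then_equalize` rescales on every application by design.
* `balanced_epoch_sample` errors on a class with zero members, naming it.

## Limitations

* CPU-only, single-process; no GPU dispatch.
* Checkpoints use the package's own `.npz` format; `export_model` supports
  that native format only.
* Only square model inputs; rectangular data must be equalized first.
* The NumPy engine targets small networks (tens of thousands to a few
  million parameters); it is not a general deep-learning framework.
* Synthetic fixtures bound what the tests can show about real microscopy
  or cytometry data (see above); on real data, expect the hyper-parameters
  to need the same manual tuning the live-control mechanism exists for.
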
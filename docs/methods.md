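# Methods

`jawdx` implements a two-branch deep-learning pipeline for diagnosing
odontogenic cysts and tumors (dentigerous cyst, periapical cyst,
ameloblastoma, keratocystic odontogenic tumor) on panoramic-radiograph-like
images, together with the synthetic phantom generator that makes the whole
pipeline testable without clinical data. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The model

A single convolutional encoder is shared by three consumers:

1. a **classification head** (global average pooling → hidden
   fully-connected layer → softmax over the class list; five classes or
   lesion/healthy in binary mode),
2. a **U-Net-style segmentation decoder** (stage-wise skip connections,
   nearest-neighbour upsampling, terminal sigmoid) predicting a soft lesion
   mask at input resolution, and
3. during pretraining, a **momentum-contrast projection head**.

The encoder is a residual design: a stride-2 stem followed by four residual
stages. Two profiles exist: `full` (stem 64, stages 256/512/1024/2048 at
stride 2 each, 2048-unit head, total stride 32 — the conventional 50-layer-
class geometry implied by a 2048-wide pooled feature) and `tiny` (stem 8,
stages 16/32/48/64 with strides 2,2,1,1, 64-unit head, total stride 8),
which is the profile every test and the acceptance script use. All
convolutions carry batch normalisation. Because the desk-scale schedules
are far too short for running-statistic EMAs to track the weights,
inference statistics are recomputed exactly from the current weights after
each training epoch (`TwoBranchNet.recalibrate_stats`); inference is then
fully deterministic, including single-image prediction.

Per-sample normalisers (GroupNorm and friends) were evaluated and rejected:
normalising each sample independently and then global-average-pooling makes
the pooled features nearly identical across samples, which removes exactly
the global-intensity statistics that distinguish a radiolucent lesion from
healthy bone.

The networks run on a small tape-based reverse-mode autodiff core
(`jawdx.nn`) written on numpy in float32: convolution via im2col,
batch-norm with gradients through the batch statistics, and the usual
pointwise/pooling ops. The core is gradient-checked against finite
differences in the test suite.

## Losses

With ground-truth label `y_k`, predicted class probabilities `p_k`,
ground-truth mask `M_k` and predicted mask `M̄_k`:

* **Classification**: mean negative log-likelihood of the true class,
  `L_CE = -(1/K) Σ_k log p_k[y_k]` (probabilities clamped at 1e-12).
* **Segmentation**: `L_MSE = (1/K) Σ_k ‖M̄_k − M_k‖²`, the squared L2 norm
  summed over pixels. A per-pixel normalisation is available
  (`mse_per_pixel`) and is on in the tiny profile, where the sum-form
  gradient magnitude (∝ pixel count) would need a compensating learning
  rate.
* **Position consistency**: for each lesion sample, the ground-truth mask
  is dilated with a disk structuring element of radius `d` drawn uniformly
  from an integer range per sample per step, reduced to the last feature
  map's resolution by block-max pooling, giving `M^d`. With the rectified
  Grad-CAM response `R` for the true class,
  `L_con = Σ_n (1 − M^d[n])·R[n] − Σ_n M^d[n]·R[n]`,
  averaged over the lesion samples of the batch; healthy samples are
  omitted. Minimising it pushes class-evidence mass out of the background
  and into (a neighbourhood of) the lesion. The annotated mask is used, not
  the predicted one. The full-scale dilation range is 6–12 px at 512×256;
  the tiny profile uses 1–3 px at 96×48 (same fraction of image width).
* Total: `w_ce·L_CE + w_mse·L_MSE + w_con·L_con`, defaults (1, 1, 1); the
  CE:MSE ratio is fixed at 1:1 and `w_con` is configurable. The constraint
  is active from the first step.

Grad-CAM channel weights (spatial means of ∂logit/∂feature-map) are treated
as constants during training, so the constraint backpropagates only through
the feature map (first order). Full second-order backpropagation through
the weights is not supported by the tape and `detach_weights=False` raises.

## Phantoms

Each frame is a bright curved "jaw band" on a darker background with:
per-image band height/curvature/thickness, a global intensity tilt, 2–3
broad bone-density patches, two dental arches of bright tooth-like blocks
with per-image count/pitch/widths/row gap, smooth large-scale texture, and
pixel noise (sd 0.03). This per-image "anatomy" matters: healthy frames
must be individually identifiable for an instance-discrimination pretext to
be well-posed, as real radiographs are.

Lesions are radiolucencies at least 0.25 darker than the underlying
background, placed inside the central 70 % × 80 % so the preprocessing crop
can never clip them, with class-coded morphology: DC — round-ish ellipse
attached to a bright crown disc; PC — small ellipse at the apex of a bright
root wedge; AB — union of 2–4 overlapping lobes with a near-isometric
bounding box (aspect kept in [0.55, 1.85] by rejection); KCOT — elongated
ellipse whose integer geometry guarantees a mask bounding-box aspect ratio
≥ 2. The mask is the exact support of the rendered radiolucency. AB and
KCOT are therefore separable by a one-line aspect-ratio rule, which
guarantees the learning task is solvable at desk scale.

Splits follow the clinical design: lesions 70/20/10 per class
(floor/floor/remainder in id order), healthy frames by explicit
(pretrain, val, test) counts; the supervised stage draws its healthy
training frames from the pretraining pool, mirroring the reuse of healthy
data across stages. Everything is a pure function of (category, seed,
spec); datasets regenerate byte-identically.

What the phantoms do **not** emulate: radiographic physics, projective
anatomy, overlapping structures, positioning artefacts, and the huge
inter-patient variability of real panoramic radiographs. Passing tests on
phantoms demonstrates that the mechanisms (losses, augmentation semantics,
metric conventions, training dynamics) are implemented correctly — not that
the method reaches any particular clinical accuracy.

## Preprocessing and augmentation

Frames are cropped to the central 80 % of width / 90 % of height (the
periphery carries no lesions) and resized to the working resolution
(512×256 at full scale; 96×48 tiny), masks re-binarised at 0.5. Cropping
away lesion pixels is an error by contract.

Three lesion-aware augmentations run on the fly during training (one chosen
uniformly per lesion sample per epoch, plus a 0.5-probability horizontal
flip for every sample):

* **flip** — mirror image and mask;
* **cut-and-paste** — lesion pixels pasted at the same coordinates onto a
  random healthy training frame; label and mask follow the lesion;
* **patch-covering** — 20 variants per lesion sample: 10 cover the whole
  lesion bounding box with a mid-gray patch (size drawn between the
  sample's own bbox and the surveyed per-dimension maxima) and are
  relabeled healthy with an emptied mask; 10 cover lesion-free tissue
  (size between surveyed minima and maxima, rejection-placed with zero mask
  overlap, a variant skipped with a warning if no placement is found) and
  keep the label. One of the 20 is drawn per use. The lesion-size survey
  runs on the training split by default (`all_splits=True` restores the
  literal survey over all lesion samples, at the cost of letting evaluation
  lesions influence augmentation statistics).

## Contrastive pretraining

Momentum contrast on healthy frames only: two augmented views per image,
query encoder + 2-layer projection head, key encoder updated as
`key ← m·key + (1−m)·query`, FIFO queue of past key embeddings, InfoNCE
with temperature 0.2. Three desk-scale adaptations (full-scale profile
keeps the reference values: m = 0.999, queue 65536):

* key momentum 0.9 and queue 64 — with only ~100 optimisation steps a
  0.999 key encoder never moves and stale keys dominate;
* the queue is warm-started with real key embeddings so the task is
  realistic from step one;
* queue keys originating from the query's own image are excluded from the
  negatives — at ~100 images the queue necessarily contains such false
  negatives, and with them the InfoNCE optimum is provably a collapsed
  (uniform) embedding.

Views are mild: crops 0.85–1.0, flip, ±5 % contrast and ±0.03 brightness
jitter, occasional light blur. Radiographs are acquired in a standardised
geometry, and radiolucency (local darkness) is the diagnostic signal, so
the aggressive crop/jitter recipes of natural-image pipelines erase all
usable view-matching signal here (measured directly: under such views even
raw-pixel nearest-neighbour retrieval of the partner view is at chance).

**Known limitation.** Even with these adaptations, ~100 gradient steps on
~100 statistically similar healthy frames leave the pretext only partially
solved; embeddings remain partially collapsed across samples. Fine-tuning
from such an encoder needs several epochs to escape that basin, and frozen
pretrained embeddings do not beat a random-init encoder under a linear
probe at this scale. The pretraining machinery is therefore verified
mechanistically (loss decreases, momentum/queue/InfoNCE contracts,
round-trip into the two-branch encoder), while the accuracy-level benefits
the clinical-scale system reports (9500 images, hundreds of epochs) are
out of reach at desk scale; the corresponding acceptance checks measure
and report this honestly.

## Training

Both branches train jointly; the encoder and classification head share one
learning rate, the decoder its own (full scale: SGD momentum 0.9 with the
1e-3 / 1e-2 rates). The tiny profile uses Adam (2e-3 / 5e-3): over short
small-batch schedules plain SGD stalls seed-dependently at the
majority-class solution, which no fixed learning rate in 1e-3…1e-1
reliably avoids. Best-validation-loss checkpointing; optional early
stopping (patience 10 at full scale; tiny runs a fixed epoch count).
Ablation switches: `no_pretrain` (random encoder init), `no_segment`
(decoder and L_MSE removed; the checkpoint contains no decoder
parameters), `no_constraint` (w_con = 0). Class weighting is off by
default, matching the clinical class imbalance being left unweighted; an
inverse-frequency option exists.

## Evaluation

One-vs-rest per-class accuracy, precision, sensitivity, specificity and F1
from the confusion matrix, with unweighted macro means; zero-denominator
metrics report 0 and are flagged. ROC/AUC per class by threshold sweep
(trapezoidal AUC; verified in tests against brute-force pair counting).
Pixel segmentation metrics pool TP/FP/TN/FN within category (per-sample
averaging would be the alternative reading; pooled was chosen and is the
default). Detection converts binary masks to 8-connected-component
bounding boxes (confidence = mean soft-mask probability in the component;
components under `min_area` discarded — 20 px at 512×256, 4 px tiny),
then greedily matches confidence-ranked predictions to unmatched ground
truths at IoU ≥ 0.5 and integrates the all-point interpolated
precision-recall curve for AP. Percentages are computed in double
precision and reported at two decimals, rounded half-up.

## Reproducibility

Every stage takes an explicit seed; the pipeline derives per-stage seeds as
`SeedSequence([global_seed, crc32(stage_name)])`, so skipping a completed
stage does not perturb later ones. All computation is single-threaded
numpy on small arrays; repeated runs are bit-identical, and the test suite
asserts end-to-end identity of the metrics report across pipeline reruns.

## Problem sizes

Tests and the acceptance script use the tiny profile throughout: 96×48
phantoms, encoder stride 8 (12×6 last feature map), datasets of roughly
50–250 frames, pretraining for 6–10 epochs and supervised training for
8–28 epochs. These sizes were chosen as the smallest at which every
mechanism is exercised and the phantom task is reliably learnable from
scratch.
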
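# Methods

## Problem and model

`skeldag` classifies short clips of human activity from 2D pose sequences:
18 COCO-layout keypoints per frame (as produced by AlphaPose-style
estimators), one performer per clip, one action label per clip. The method
has three stages.

**Skeleton graph.** The 18 joints form a directed tree rooted at the nose,
edges pointing from parent to child (shoulder → elbow → wrist, …). Edge
`e_i` is the edge targeting joint `i`; a virtual self-loop `e_0 = (0, 0)`
at the root pads the 17 anatomical edges to 18 so the edge-by-joint
incidence matrices are square. The source matrix `S` marks each edge's
source joint, the target matrix `T` its target joint. `S` entries are
divided by the source joint's out-degree, `T` entries by the target
joint's in-degree. For this skeleton the nose and neck each source four
edges (counting the self-loop), so `S` has nonzero values {0.25, 1}
exactly; every joint is the target of exactly one edge, so the normalized
`T` is binary. Two deliberate readings are baked in here:

* *Normalization axis.* "Row" normalization of an edge-by-joint incidence
  matrix is a no-op (one source per edge). We normalize per joint
  (by degree), which is what produces the 0.25 entries; the literal
  row-normalized variant is available via `DagMatrices.row_normalized()`.
* *Edge orientation.* A global "joint i−1 → joint i" rule only holds along
  kinematic chains; the parent→child orientation in a nose-rooted tree is
  the one that gives the nose and neck out-degree 4 and hence the 0.25
  value set. The virtual edge counts toward the nose's out-degree
  (otherwise its entries would be 1/3).
* With one incoming edge per joint, degree normalization leaves the target
  matrix binary; a 0.25 value can only arise in the source matrix. We
  follow the arithmetic.

**Features.** Every clip is standardized to 300 frames (configurable).
Four base matrices of shape `2T × 18` hold x and y rows per frame: joint
coordinates `F_v`, limb vectors `F_s` (child minus parent; the virtual
edge column is zero), and their forward frame differences `F_mv`, `F_ms`
(the final frame's difference rows are zero-filled, which keeps the shape
without inventing motion). Rows interleave x and y per frame by default,
so a `(9, 1)` convolution kernel spans ~4.5 frames of alternating
coordinates; a blocked layout (all x rows, then all y rows) is
config-selectable. Each base feature is expanded through the DAG:
joint-indexed features as `F·Sᵀ`, `F·Tᵀ` (columns become edges),
edge-indexed features as `F·S`, `F·T` (columns become joint aggregates),
so the three channels of every sub-feature share one column index space;
the literal transposed form everywhere is config-selectable
(`transpose_all`). Triplets stack into two stream tensors of shape
`4T × 18 × 3`:

| stream  | joint part (rows 0..2T−1) | skeleton part (rows 2T..4T−1) |
|---------|---------------------------|-------------------------------|
| spatial | (F_v, F_sin, F_sout)      | (F_s, F_vin, F_vout)          |
| motion  | (F_mv, F_msin, F_msout)   | (F_ms, F_mvin, F_mvout)       |

**Classifier.** Each stream's two sub-features pass through separate
10-layer towers (weight sharing optional). A layer applies: DAG expansion
of the activation (`[X, X·Sᵀ, X·Tᵀ]` along channels — tripling the channel
count, which is the only reading consistent with the 64→192, 128→384,
256→768 layer inputs; skipped at layer 1), a per-position linear map down
to the layer width, batch-norm, ReLU, a `(9,1)` convolution over the time
axis (stride 2 at layers 5 and 8, padding 4), batch-norm, ReLU. Default
widths are 64,64,64,64,128,128,128,256,256,256. Tower outputs are
globally average-pooled over time and joints (the pooling operator behind
the final flatten is unstated upstream; global average pooling is the
standard choice for position-agnostic evidence and matches the 2×256=512
head width), concatenated, and mapped linearly to one logit per class
(49 by default) with a softmax on top. Class-score fusion averages the
spatial and motion probability vectors; prediction is the argmax with
ties broken toward the lower class index.

## Training

Cross-entropy loss (implied by the softmax output), SGD with momentum 0.9,
batch size 32, learning rate 0.01 by default with a ×0.5 step decay every
10 epochs — the optimizer family and batch size are fixed by the design;
the learning-rate schedule and momentum coefficient are unstated upstream
and config-exposed. All randomness (init, batch order) derives from one
integer seed; identical seeds reproduce loss traces bit-for-bit on one
device. Training refuses single-class datasets and aborts on non-finite
loss.

Two implementation details matter on small datasets:

* An extra batch-norm on the raw 3 input channels of each tower
  (`input_norm`, on by default) absorbs the pixel-scale offsets of raw
  coordinates (means ≈ frame centre, variances ≈ body extent), which
  otherwise condition the first linear map badly.
* With few optimizer steps the exponentially averaged batch-norm running
  statistics lag the trained parameters, so evaluation-mode outputs are
  stale. `recalibrate_batchnorm` recomputes the running statistics
  exactly (average of batch statistics over one forward pass) before each
  validation and at the end of training. When a validation set is given,
  the best-validation epoch's parameters are kept.

The network is implemented directly in NumPy (forward and backward passes,
including the batch-norm and strided-convolution gradients); every layer's
backward pass is verified against central finite differences in float64 in
the test suite, and the convolution is a single im2col GEMM per layer.

## Synthetic data

The generator emulates multi-class clips of 2D joint trajectories: an
upright base pose in a 1920×1080 frame, per-class "motion programs" that
oscillate a limb group sinusoidally with class-specific amplitude
(35 + 12·class px) and frequency (1 + 0.75·class cycles/clip), Gaussian
pixel noise (default sd 2 px), and simulated detector dropout (default 2%
of joint-frames collapse to the origin with confidence ≈ 0). Sinusoids
were chosen over random walks because their motion statistics are in
closed form — the finite difference of `A sin(2πft/T)` has variance
`≈ (πfA/T)²·2`, so e.g. frequencies 1 vs 4 give a 16× motion-variance
ratio, which the tests check numerically. Subjects and cameras are
assigned round-robin so both cross-subject and cross-view splits are
exercisable. The seed fully determines the dataset.

What this does *not* emulate: perspective and camera viewpoint changes,
inter-subject body-shape and style variation, correlated pose-estimator
failures, occlusions, and background people. Passing tests therefore show
that the pipeline is implemented correctly and can learn separable
kinematics end-to-end — not that the published accuracy on real
benchmark video reproduces. That result requires the restricted-access
corpus and roughly 1.5 days of GPU training per stream, and is out of
scope here.

## Problem sizes used in the checks

The structural checks (graph values, 600×18 features, full Table of layer
shapes with the 64/128/256 widths, 512-wide head, 49-way softmax) run the
full-size architecture. The learning-sanity check trains both streams for
15 epochs on a seeded 5-class dataset, 50 clips per class, split
cross-subject — with clip length 60 frames and reduced channel widths
(8,…,32), sizes this package adopts for its CPU-scale demonstrations; the
architecture, expansion rule, optimizer and batch size are unchanged.
Both streams reach ≥ 90% test accuracy and fused scores do not fall below
either stream.

## Numerical choices and edge cases

* Clip standardization: loop-padding short clips (frame `n mod T`)
  preserves motion statistics; zero-padding would inject spurious motion
  spikes. Long clips sample `floor(i·T/L)`. Idempotent at the target
  length.
* Joint repair: coordinates with confidence < 0.05 are linearly
  interpolated per joint over time; boundary gaps hold the nearest valid
  value; never-valid joints take the neck trajectory and are flagged.
  Confidence is used only for person selection and repair, never as a
  model input.
* Metrics: one-vs-rest counts per class; precision of a never-predicted
  class is defined as 0 and the class flagged, keeping macro averages
  defined. Macro (unweighted per-class) averaging is the default; micro
  is available. One-vs-rest accuracy and specificity sit near 100% under
  many classes because true negatives dominate — they should not be read
  as multiclass accuracy, which is reported separately.
* Batch-norm ε = 1e-5; He initialization; float32 arithmetic in the
  network (float64 inputs are honoured for gradient verification).
* `fuse_scores` requires softmax-normalized inputs and equal lengths.

## Known limitations

* CPU-only; no GPU kernels or mixed precision. Full-width training at
  realistic dataset sizes is out of reach — the package targets method
  correctness, ablation tooling and desk-scale experiments.
* Single-person clips only; multi-person interaction classes are not
  modelled.
* The upstream description leaves several points ambiguous (row layout of
  x/y, expansion orientation for edge-indexed features, pooling operator,
  tower weight sharing, learning-rate schedule); each is resolved with a
  documented default and a config switch where alternatives are sensible.
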
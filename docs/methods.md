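# Methods

This note documents the models, procedures and numerical choices behind
`echophase`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic experiments do and do not show.

## The classification problem

A transthoracic echo cine loop shows the left ventricle (LV) contracting
and relaxing once per beat. The end-systolic (ES) frame has the smallest
LV cross-section, the end-diastolic (ED) frame the largest; everything in
between is "Non-ESED". The package frames phase detection as image
classification: a frame goes in, a phase score comes out. No LV
segmentation, ECG gating or temporal context is used — the classifier must
read the cavity geometry straight from the pixels.

## Synthetic data generator

Clinical echo datasets are access-restricted, so the package ships a
seeded generator that reproduces the properties the classifier actually
exploits:

- a bright cone-shaped scan sector (apex top-centre, half-angle 33°,
  radius 0.93·H) on a dark background;
- multiplicative speckle: pixel intensities are scaled by
  `(1 − s) + s·R` where `R` is Rayleigh-distributed with unit mean and
  `s = speckle_scale` (default 0.5; 0 gives a clean phantom, 1 fully
  developed speckle);
- a dark elliptical LV cavity whose area is a configured fraction of the
  sector area: 0.05 at ES, 0.22 at ED, uniform in [0.09, 0.17] for
  Non-ESED. The ES/ED gap of 0.17 is deliberately generous — roughly the
  relative area change of a healthy ventricle — making the binary task
  cleanly separable;
- jittered cavity centre and aspect ratio (0.55–0.70) so frames are not
  copies of one another.

Frames default to 112×112 8-bit grayscale, mirroring the common
downsampled-video format, and are resized to the model's 150×150 input by
the preprocessing stage — intentionally exercising the resize path real
multi-source data needs. Each synthetic "video" contributes exactly three
frames (ES, ED, Non-ESED); the Non-ESED frame index is drawn uniformly
from the video's remaining frames.

Tracing metadata is generated in the EchoNet `VolumeTracings` CSV dialect:
per frame, one long-axis row (apex end to mitral end) followed by
`n_chords` (default 20; real tracings vary, and the count is
configurable) short-axis chord rows whose endpoints lie on the drawn
ellipse. Coordinates are 0-based `(x=column, y=row)`, rows increasing
downward; the file round-trips floats exactly (written at 17 significant
digits, read with round-trip parsing).

**What the generator does not emulate:** anatomy beyond a single
elliptical cavity (no myocardium texture gradients, valves, papillary
muscles), probe-dependent point-spread functions, view geometry
(two- vs four-chamber), or inter-patient variability. Passing the
synthetic-recovery tests therefore shows the pipeline is *correct and
able to learn area-coded phase structure* — it does not certify clinical
accuracy, which depends on data this package does not ship.

## Augmentation and preprocessing

Training-time augmentation applies, in order: rescale (×1/255), a shear
along x with factor drawn uniformly from ±0.2, a zoom with factor uniform
in [0.8, 1.2] about the image centre, and a horizontal flip with
probability 0.5. Geometric transforms use bilinear interpolation with
edge replication (zooming out never paints artificial black borders). The
axis and distribution of the shear, and the fill rule for zoom-out, are
package choices; only the intensities (0.2/0.2) and the flip are fixed by
the recipe. Test-time preprocessing is deterministic: optional
annotation-strip crop, rescale, bilinear resize to 150×150, and a mean
(box) filter — "linear and mean filtering" is implemented as a single box
filter with configurable odd kernel (default 3).

## Tracing-based cropping

Per tracing, three points matter: the long-axis top `(x_t, y_t)`, the
long-axis bottom `(x_b, y_b)` and the bottom-of-image point
`(x_d, y_d) = (x_b, H−1)` — the vertical drop to the last row is the only
reading that keeps the second midpoint's x-coordinate meaningful. The
dataset-level midpoints average the per-frame midpoints

    M1 = (mean (x_t+x_b)/2, mean (y_t+y_b)/2)
    M2 = (mean (x_b+x_d)/2, mean (y_b+y_d)/2)

over the **training** tracings only, and are applied unchanged to
validation and test frames — the crop is part of the frozen preprocessing,
so no held-out geometry leaks into it. The retained band is rows
`[Y1, Y2)` (mid-cavity through the mitral region); an optional
`half_width` also restricts columns about `X1`. Midpoints are stored
unrounded; rounding (half away from zero) happens only at crop time, and
crops are contiguous sub-grids — never resampled. Whether to crop columns
at all is left to the caller (`half_width="full"` by default), since the
vertical band is what carries the phase signal.

## The classifier

A deliberately small CNN with nine named layers: input, three 3×3 valid
convolutions with ReLU (default 32/64/128 filters), each followed by a
2×2 max-pool, one hidden dense layer (default width 128, ReLU), and an
output layer — a single sigmoid unit for the binary task, a 3-way softmax
for the 3-class task. The flatten between the last pool and the dense
layer is index bookkeeping, not a layer. On a 150×150×1 input the
feature-map trace is 148 → 74 → 72 → 36 → 34 → 17; each 2×2 pool on an
even map keeps exactly one activation in four. There is no dropout:
regularisation comes from the loss and augmentation. Valid (unpadded)
convolutions match the minimalist design; the filter counts and dense
width are not dictated by the recipe and default to a standard doubling
ladder, all configurable.

The forward and backward passes are hand-written NumPy: convolutions as
im2col + one GEMM per layer (the im2col buffer is laid out
kernel-row × kernel-column × channel so gather/scatter moves contiguous
channel blocks), max-pool backward routes each gradient to the first
position attaining the window maximum, and Adam with the standard
bias-corrected moments does the updates. Weights are Glorot-uniform from
a seed; parameters are float32 (4,827,905 of them at the default
configuration). Gradients of every layer are verified against central
finite differences on a float64 copy of a small model in the test suite.

## The loss

The training objective is a regularised mean squared error:

    L(χ, M) = MSE(χ, M) + β · mean(χ, M),   β > 0

where `mean` is the *signed* mean residual `(1/n) Σ (τ(xᵢ) − M(xᵢ))`.
The term is implemented exactly as defined: it penalises systematic
under-prediction and rewards over-prediction, and the total loss can go
negative when the model over-predicts on average — an intentional
fidelity choice, with an absolute-mean variant (`mean_mode="abs"`)
available for ablations. The analytic per-element gradient is
`−2(τ−M)/n − β/n`. For the 3-class task labels are one-hot rows and the
losses average over classes then instances (a flat element mean).
Baselines: MSE, MAE, and cross-entropy (predictions clipped to
(1e-7, 1−1e-7) before the log), plus L1/L2 penalties of strength 0.1 on
all conv/dense kernels (not biases) paired with the MSE data term.

## Training and evaluation protocol

Adam with learning rate 1e-5, batch size 10, no early stopping; a
stratified 10% validation split unless one is supplied. The per-epoch
history records train/validation loss and AUC (full-dataset forward
passes at the end of each epoch; the configured weight penalty, if any, is
included in reported losses, while `evaluate` reports the data term on
the held-out batch).

ROC AUC uses the midrank Mann–Whitney formula — exactly the probability
that a random positive outscores a random negative with ties counted one
half — and is checked against the O(n²) all-pairs count. The 3-class AUC
is the unweighted (macro) mean of the three one-vs-rest AUCs; macro
precision/recall use argmax predictions, binary precision/recall a 0.5
threshold (package choices — the protocol does not pin them down). With
no positive predictions, precision is reported as 0 with a warning.

Harnesses: stratified k-fold cross-validation (default k=5) reporting the
arithmetic fold mean; a β sweep training one model per β with shared seed
and splits; and the cropping ablation, which trains identical
configurations on raw vs cropped frames with midpoints computed from the
training split. The ablation's synthetic stress test paints bright
random elliptical clutter *outside* the crop band, so the uncropped arm
faces label-independent nuisance variation the cropped arm never sees.

## Determinism

Every stochastic component takes a seed or an explicit
`numpy.random.Generator`: frame synthesis, augmentation draws, weight
initialisation, batch shuffling, fold assignment. Identical configs and
seeds reproduce byte-identical PNGs/manifests and bit-identical training
losses on CPU (single-threaded BLAS order is fixed).

## Problem sizes in the test suite and acceptance script

End-to-end checks use sizes chosen to demonstrate the properties at desk
scale: phase recovery trains the full-size model on 300 synthetic ES/ED
frames (150 videos, 75/25 split) for 6 epochs on each of 3 seeds —
held-out AUC saturates within the first epochs on this cleanly separable
data — and the cropping ablation uses 60 videos (180 frames, 3 classes),
5 epochs, 2 arms × 3 seeds. Unit tests use a miniature 22×22-input model
with 2/3/4 filters, which exercises identical code paths.

## Known limitations

- The synthetic phantom's simplicity means headline AUCs near 1.0 say
  nothing about clinical performance; they validate machinery, not
  medicine.
- The signed mean term makes the loss unbounded below for systematic
  over-prediction; at β ≤ 0.6 and lr 1e-5 this is benign in practice, but
  large β with aggressive optimisers could exploit it (use
  `mean_mode="abs"` to rule it out).
- With the cautious default learning rate, ranking (AUC) converges well
  before score calibration: thresholded precision/recall can read 0 early
  in training while AUC is already near 1.
- Only Adam is implemented; convolution stride is fixed at 1 and pooling
  non-overlapping, per the architecture definition.
- `n_classes` supports the studied 2- and 3-class tasks only.
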
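# Methods

## Problem and model

Clinical quantification of left-ventricular mass (LVM) needs landmark
measurements from several standard echocardiographic views (A2C, A4C,
PLAX, PSAX), but per-view labelled datasets are expensive. This package
treats each view as a *task* in a meta-learning problem: a single
segmentation-style network is meta-trained on three views and adapted to
the fourth from a handful (k) of labelled frames.

Landmark detection is cast as heatmap regression. Each of the four
landmarks becomes one output channel whose training target is a 2D
Gaussian of standard deviation sigma = 7 px centred on the point, peak
amplitude 1. Peak-1 (rather than unit-mass) amplitude is the dominant
convention in heatmap regression and makes decoding threshold-free: the
predicted point is the channel argmax, ties broken toward the lowest
(row, col). An optional Gaussian matched filter (`smooth_sigma`) before
the argmax implements a "centre of the detected region" decode for noisy
maps; it is off by default so the exact argmax contracts hold. An
optional 3x3 centroid refinement gives subpixel output.

## Backbone

The framework is model-agnostic: meta-learners see only a
`loss_and_grad(params, batch)` contract plus a body/head partition of the
parameters. The reference backbone is a 3-level encoder-decoder with skip
connections (a miniature U-Net: widths w, 2w, 2w with w = 4 by default,
~1.8k parameters) implemented directly on NumPy arrays with explicit
backward passes, so the whole protocol runs on one CPU with no deep
learning framework. Activations are leaky ReLU (slope 0.01): with hard
ReLU, long meta-training runs can drive units dead, after which test-time
adaptation cannot recover (the network emits flat heatmaps). The "head"
is the final 1x1 projection to the 4 landmark channels — the smallest
adaptation set consistent with ANIL's definition. Arithmetic is float32
by default (about 4x faster on CPU); float64 is available for gradient
checking. Inputs are normalised to [0, 255] upstream and divided by 255
inside the network.

## Meta-learners

All four learners are strictly first-order; nothing backpropagates
through the inner-loop trajectory.

- **FOMAML** — inner: `theta_k = theta_{k-1} - alpha * grad L_support`;
  outer: the query-loss gradient evaluated at the adapted parameters.
- **Meta-SGD** — one learnable rate per scalar parameter, initialised to
  the inner rate (0.03) and meta-learned thereafter; the inner step is
  `alpha ⊙ grad`. The alpha meta-gradient uses the same first-order
  approximation as FOMAML (inner gradients treated as constants), giving
  `dL_q/dalpha = -g_query ⊙ sum_k g_inner_k`.
- **Meta-Curvature** — inner gradients of each C_out x C_in x d filter
  are preconditioned by a Kronecker-factored matrix
  (M_o ⊗ I)(I ⊗ M_i ⊗ I)(I ⊗ I ⊗ M_f), applied as three mode-wise
  contractions without materialising the dense product; vector parameters
  use a single square factor. Factors start at identity so training
  starts exactly as FOMAML; factor meta-gradients use the same
  first-order scheme. The scalar inner rate multiplies the preconditioned
  step so that identity factors reproduce FOMAML exactly.
- **ANIL** — the inner loop adapts only the head; body tensors are passed
  through untouched (bit-identical arrays). The outer loop meta-updates
  both.

Query losses are aggregated across the tasks of a meta-batch by
summation. The outer update is either the plain gradient rule
`x <- x - beta * g` or an Adam step with rate beta; Adam at 5e-3 is the
default, matching the training protocol, while the SGD mode keeps the
textbook update testable in closed form.

## Protocol and parameters

| parameter | default | meaning |
|---|---|---|
| sigma | 7 px | Gaussian label width |
| inner rate / steps (meta-train) | 0.03 / 10 | per-task adaptation |
| inner rate / steps (meta-test) | 0.05 / 100 | k-shot fine-tuning |
| outer optimizer / rate | Adam / 5e-3 | meta-update |
| k | 5, 10, 20, 30 | few-shot sizes (baseline: 100) |
| image size | 64 (256 to mirror clinical frames) | phantom resolution |

Meta-training samples one episode from each of the three training views
per iteration (3-way); an "epoch" is a configured number of
meta-iterations, since the episodic epoch size is a free choice. Every
`val_every` iterations the current initialisation is adapted on a fresh
validation episode per training view (meta-train inner settings) and
scored by mean pixel accuracy of the binarised heatmaps on the episode's
query set; the checkpoint with the highest validation accuracy is kept.
At test time only the inner loop runs (no outer update); Meta-SGD adapts
with its learned per-parameter rates, the other learners with the
configured test rate. The supervised baseline trains the same backbone
with Adam 5e-3 and minibatches, selecting the best epoch by the same
validation accuracy. Rotation augmentation (0-30 degrees, bilinear, exact
point transform) is available for training data but off by default on
phantoms, whose orientation is already sampled per draw.

## Synthetic phantoms

The phantom generator replaces clinical recordings: each view family is a
sector-masked (fan from the top centre), speckled image containing an
elliptical chamber with a bright wall. Geometry (centre, axes,
orientation) is jittered per sample; landmarks follow deterministically —
boundary points at view-specific parametric angles for A2C/A4C/PSAX, four
collinear points crossing the walls for PLAX so that consecutive segments
play the roles of IVS, LVID and LVPW. Speckle is multiplicative uniform
noise (level 0.35 by default) on the smoothed template, the simplest
texture that makes argmax decoding nontrivial. Every output is a pure
function of (spec, seed).

What the phantoms do *not* emulate: true speckle statistics and probe
artifacts, anatomical shape variability, low-contrast boundaries,
patient-level correlation between frames, and physical pixel spacing.
Passing tests therefore demonstrate that the algorithms and protocol are
implemented correctly and that meta-learning transfers across these
synthetic task families — not clinical-grade accuracy.

## Metrics

MDE is the mean Euclidean error over matched points; SDR the fraction of
points within a threshold; MAE the undirected angle difference between
predicted and reference segments folded into [0, 90] degrees (matching
the |cos theta| treatment of orientations in SAS). SAS =
100(alpha |cos theta| + (1 - alpha) e^(-beta d)) with defaults
alpha = 0.5, beta = 0.1 px^-1; d is the symmetrised mean of the two
midpoint-to-infinite-line distances, which is swap-invariant and reduces
to the ordinary separation for parallel lines. Dice and mean pixel
accuracy binarise each heatmap channel at half its own peak; two empty
masks count as Dice 1. Non-PLAX views use generic consecutive-pair
segments for the line metrics.

## LVM conversion

Devereux: LVM = 0.8 * 1.04 * ((IVS + LVID + LVPW)^3 - LVID^3) + 0.6 g;
area-length: LVM = 1.05 * ((5/6) A1 (a + d + t) - (5/6) A2 (a + d)) g,
both in the standard ASE constant set, exposed for variant conventions.
Pixel-to-cm calibration is a required input — never defaulted, because
image data carries no physical spacing. A1 = A2 with t = 0 is accepted as
the degenerate zero-wall case; A1 < A2 is rejected.

## Problem sizes and numerical choices

The end-to-end few-shot experiments run at desk scale: 64 x 64 phantoms,
width-4 backbone, 200 meta-iterations, k-shot adaptation with the
protocol's 0.05/100 test settings, 5 paired replicate seeds in both the
acceptance test and the acceptance script. The supervised-baseline sanity checks use
32-pixel phantoms with a few hundred Adam steps. Inner-loop gradients are
clipped to a global norm of 10 (config-exposed): the clip never triggers
in healthy training but prevents the fixed-rate inner loop from running
away late in float32 meta-training. Degenerate inputs are
handled explicitly: flat heatmap channels warn and decode to the
tie-break origin; zero intensity range maps to zero; coincident
consecutive landmarks make the affected segment metrics degrade to their
worst values (MAE 90, SAS 0) rather than crash; non-finite losses or
gradients abort adaptation with a diagnostic.

## Known limitations

The learnable-rate and curvature meta-gradients are first-order
approximations (exact second-order paths are out of scope). Meta-SGD
with the plain SGD outer rule can diverge on large-gradient problems —
the Adam outer mode is the stable default. Reported phantom MDE values
are not comparable to clinical-data results; the biplane LVM model and
the statistical significance analysis of view-level comparisons are not
implemented.
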
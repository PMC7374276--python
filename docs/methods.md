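# Methods

## The counting model

`cellcount` counts cells on phase-contrast microscope frames by regressing
a **redundant count map**. Given one-pixel expert marks (one per cell), the
training target for a frame of size H × W is a grid of size
(H+2p) × (W+2p), p = (k−1)/2, whose pixel (i, j) holds the number of marks
inside the k × k window centred on it (k odd; 65 by default, so p = 32 and
k² = 4225). Equivalently, the target is the mark-impulse image convolved
with a k × k kernel of ones at full-convolution extent. Every cell — border
cells included, which is why the image is zero-padded by p — contributes to
exactly k² target pixels, so

    count = sum(map) / k²

holds exactly for targets, and approximately for predicted maps. Because
each cell is counted k² times, independent per-pixel prediction errors
partially cancel in the sum; this redundancy averaging is what makes the
approach accurate on clustered, non-convex cells that defeat
segmentation-based counting. Counts are kept real-valued end to end;
rounding is presentation-only, so that signed fractional errors can also
cancel across frames of a series.

The map is predicted by a fully convolutional network in the Count-Ception
family: a 3 × 3 stem, five inception blocks (parallel 1 × 1 and 3 × 3
convolutions, channel-concatenated), a 1 × 1 chokepoint that narrows the
channel dimension, two large same-padded convolutions that extend the
receptive field, and a final 1 × 1 chokepoint down to the single-channel
map. All convolutions use same padding, so spatial size is preserved end
to end — a structural requirement of the sum rule. Batch normalization
follows every convolution except the output layer; activations are ReLU;
weights are Glorot-uniform from a single seed. The nominal receptive field
is 3 + 5·2 + (L₁−1) + (L₂−1) and the two large kernels L₁, L₂ are derived
from k so that it reaches at least k (k = 65 → 27 and 27; k = 33 → 11 and
11); building a model whose receptive field is below k is a configuration
error, because an output unit could not see the window it must count.

The "chokepoints" reduce the channel dimension, not the spatial one: the
sum rule needs spatial size preserved, so a spatial reduction reading is
structurally impossible here. Exact layer widths are free parameters of
`ModelSpec`; the method's correctness depends only on receptive field and
size preservation. Two instantiations are provided: `ModelSpec.reference`
(stem 64, branches 16+16, chokepoint 16, large convolutions 32/16) for
production-scale frames, and `ModelSpec.compact` (8 / 4+4 / 4 / 8/8) used
throughout the test suite.

### Implementation of the network

No deep-learning framework is used: the layers, backpropagation and the
Adam optimizer are implemented directly in float32 numpy. Convolutions
dispatch on kernel size — 1 × 1 as a channel matmul, small kernels via
im2col + BLAS gemm, kernels ≥ 7 in the Fourier domain (forward pass, input
gradient and weight gradient are each one batched FFT product; FFT sizes
are padded to fast lengths and chosen so circular wraparound cannot
occur). The three paths are numerically equivalent and are cross-checked
against each other and against finite differences in the test suite.
Batch normalization with batch size 1 normalizes per channel over the
spatial axes and keeps running statistics (momentum 0.1) for inference.

## Training protocol

Following the original acquisition setup, full frames (1040 × 1392) are
split into four quadrants along floor(H/2)/floor(W/2) to bound memory, and
each quadrant is zero-padded by p and trained/predicted independently; the
frame count is the sum of the four quadrant counts. A cell whose *body*
straddles a quadrant border may be counted fractionally in both quadrants
by a real model — an accepted error source of the method, not corrected by
overlap tiling. Its annotation pixel, however, lies in exactly one
quadrant, so target bookkeeping is exact.

Training uses Adam (learning rate 10⁻³), batch size 1, an 8:2
train/validation split, optional ×4 rotation augmentation (90°/180°/270°
with exact annotation remapping), and early selection of the epoch with
the lowest validation loss (first occurrence on ties). Inputs are BT.601
grayscale, scaled to [0, 1]. All randomness (initialization, shuffling,
splits) flows from one seed; two runs with the same seed produce identical
loss curves.

**Loss.** The per-pixel loss is configurable between mean absolute error
(the default, matching the L1 loss of the Count-Ception lineage) and mean
squared error. Under the short schedules used in this package's test
protocol (≤ 50 epochs), L1's median-seeking behaviour on the zero-inflated
count-map distribution produces a systematic undercount (pilot runs:
≈ 17 % mean relative count error, all signed errors negative), while the
mean-seeking squared-error loss is unbiased for count sums and reaches
≈ 4 %. The scripted evaluation therefore trains with `loss="mse"`; users
reproducing long L1 schedules can switch back with one argument.

## Red-fluorescent counting

Frames carrying a red fluorescent reporter (e.g. an ER-stress biosensor)
are RGB: green/blue carry the phase-contrast image, red carries the
fluorescence overlay, which is dark except where the reporter is
expressed. Red-positive cells are counted by binarizing the red channel at
a user threshold t ∈ [0, 255] (inclusive ≥, an explicit convention),
zeroing all grayscale pixels outside the mask, and counting the masked
image with the ordinary model. Masked-out pixels become 0, the same value
as the zero padding the model sees at every frame border during training.
The red count is not mathematically guaranteed to be ≤ the total count
(both are independent model outputs), and the implementation does not
force it. The percentage of red cells is 100·red/total, undefined (an
error, not 0) when the total is non-positive.

A masked frame is mostly black, which places it far from the intensity
distribution of the plain frames the model is fitted on. The coupling is
concentrated in the batch-normalization statistics: with batch size 1
those are exponential averages over training images, and experiments in
this package showed that (a) a model fitted only on plain frames
over-counts masked frames badly, (b) naively mixing masked examples into
training drags the averaged statistics toward the masked distribution and
mis-calibrates the plain frames instead, and (c) per-image statistics at
inference amplify noise on near-empty frames into spurious counts. The
protocol that resolves this is a standard frozen-normalization fine-tune:
after the main training phase the normalization statistics are frozen and
used in the training forward pass (so training optimizes exactly the
inference-time function), and the network is briefly fine-tuned at a
reduced learning rate on a mixture of plain and red-masked quadrants —
the masked quadrants' targets counting only the reporter-positive cells.
This calibrates the masked domain without disturbing the statistics the
dense frames rely on.

The fine-tune additionally computes its loss on the **zero-clipped**
output rather than the raw map. Count inference sums max(raw, 0), so a
raw output that merely fluctuates around zero over large empty (masked)
areas leaves a strictly positive count floor after clipping — roughly
σ/√(2π) per pixel — which shows up as a constant spurious offset of a
few cells per masked frame. Training the clipped output lets the raw map
settle slightly below zero over empty regions (zero loss, zero gradient
there), eliminating the floor, while a small leak term (slope 0.1 below
zero where the target is positive) keeps currently-missed cells
learnable. On the positive side the loss is identical to plain MSE.

## Time-course statistics

Batch counts join a sample sheet (group, dose, field of view, time index)
into tidy records. Because starting red percentages differ between wells,
each field's series is baseline-subtracted (first value subtracted from
all). The endpoint comparison takes, per field, the red-percentage change
between first and last time points, compares every pair of groups with a
two-sided Mann–Whitney test and Bonferroni-corrects over the number of
pairs (C(4,2) = 6 for four groups). The Mann–Whitney implementation uses
mid-ranks for ties and reports U = min(U_a, U_b); the null is enumerated
exactly (all C(n, n_a) assignments) when the combined sample size is ≤ 12
and approximated normally with tie and continuity corrections above that —
a fixed, documented switch chosen for determinism rather than delegated to
a library's internal heuristics. Poisson GEE regression on the same tidy
output is deliberately out of scope; the export format is ready for any
standard GEE tool.

## The synthetic scene generator

All tests run on generated phase-contrast-like scenes, since the original
experimental frames are not distributed. Cells are radially perturbed
ellipses (low-order harmonic perturbation; the `shape_irregularity` knob
verifiably increases outline complexity) with a dark interior ≈ 65 and a
2 px bright halo ≈ 180 on a noisy mid-gray background (120 ± 8 on the
0–255 scale). Placement mixes a Thomas cluster process (uniform parents,
Gaussian offspring, 60 % of cells by default) with uniform placement;
overlapping bodies are allowed — the hard case the method exists for —
while integer centroid annotations keep a 2 px minimum separation so marks
stay distinct. A configurable fraction of cells (default for the red
studies: 30 %, a typical transient-transfection efficiency) is painted
into the red channel over the cell's full optical footprint (the reporter
fills the cell, rim included) at an intensity drawn from 150–230 over a
dark (~10) fluorescence background, so that the 30 and 100 thresholds
used in practice separate signal from background cleanly.

The default test suite is 16 training + 4 validation frames (the 8:2
bookkeeping of a 20-frame labelled series) + 8 held-out frames of
128 × 128 px with Poisson-distributed cell counts around 40 per frame
(well-to-well seeding variation; a constant-count suite would let a
trivial constant predictor pass the recovery test). Scenes are
bit-reproducible from one master seed.

What the generator does **not** emulate: real phase-contrast optics
(shade-off, illumination gradients, focus drift), debris, mitotic and
apoptotic morphologies, or fluorescence bleed-through. Passing the
recovery tests therefore demonstrates that the pipeline's machinery is
correct and trainable, not that the shipped configuration matches expert
accuracy on real microscope series — for that, the published 26-frame
validation statistics are reproduced exactly from the distributed count
pairs instead.

## Scaled-down evaluation sizes

The scripted evaluation (`scripts/acceptance.py`) and the training test
use the compact network at k = 33 on the 128 × 128 suite with a 50-epoch
budget split into 35 main epochs on the plain quadrants (64 samples per
epoch) and 15 frozen-normalization fine-tune epochs on the plain
quadrants plus the red-masked quadrants with their three right-angle
rotations (320 samples per epoch — the rotations enrich the scarce masked
domain; learning rate 2·10⁻⁴, five times below the main rate). Recovery
accuracy under this protocol varies a few percentage points with the
random suite realization, as expected for a stochastic experiment of this
size. The whole
protocol trains in a few CPU-minutes while exercising every code path of
the full-scale configuration; the full-scale reference model (k = 65,
1040 × 1392 frames) differs only in layer widths, kernel sizes and
schedule length.

## Numerical choices and degenerate inputs

- Count targets are built with integer integral-image arithmetic — exact,
  no floating-point accumulation.
- Predicted maps are clipped at 0 before count inference; raw network
  outputs may be negative.
- Odd frame dimensions split as floor/ceil quadrants; 1-pixel frames are
  rejected for tiling.
- Annotations exactly on the frame edge are valid (bounds are half-open);
  a point outside raises with the offending index. Duplicate marks are
  legal (two cells may share a pixel) but warn.
- 8-bit rasters only; other bit depths are rejected rather than rescaled
  because the red threshold semantics are defined on 0–255.
- Checkpoints embed both the architecture and the count-map spec, so a
  model cannot be asked to infer with a mismatched k.

## Known limitations

- The numpy training loop is single-image and CPU-bound; it is sized for
  the compact configuration, and a full-scale 400-epoch run, while
  functional, is far slower than a GPU framework.
- Quadrant-border cells can be double- or half-counted by a real model
  (see above).
- Red counting inherits any model bias twice (mask plus count); on very
  sparse red populations the relative error of small counts is
  intrinsically high.
- The service is synchronous and unauthenticated by design; batch work
  belongs to the CLI.
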
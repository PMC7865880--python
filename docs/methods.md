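# Methods

## Problem and model

`oinose` classifies odors from a 10-sensor metal-oxide (MOS) e-nose
array of the PEN3 type: each measurement is a 10 × 120 matrix of
dimensionless response ratios sampled at 1 s over a 120 s exposure.
The classifier is a deliberately small depthwise-separable 1-D CNN
sized for shift-only integer hardware:

| stage | shape | notes |
|---|---|---|
| input | 1×120×10 | the 10 sensor rows become 10 independent channels |
| depthwise conv 1×3 | → 1×118×10 | valid, stride 1, ReLU |
| pointwise conv 10→6 | → 1×118×6 | ReLU |
| max-pool 1×2 | → 1×59×6 | stride 2 |
| depthwise conv 1×2 | → 1×58×6 | ReLU |
| pointwise conv 6→10 | → 1×58×10 | ReLU |
| max-pool 1×2 | → 1×29×10 | flattens channel-major to 290 |
| fully connected 290→7 | → 7 | softmax in float; raw argmax in int8 |

Factoring a standard convolution into a per-channel (depthwise) stage
and a 1×1 cross-channel (pointwise) stage cuts the conv weight count
from 316 (standard reference net, with biases) to 162, i.e. for a
separable pair with C_inter = C_in the weight-count ratio is
1/C_out + 1/(W_K·H_K).  A same-footprint standard-conv baseline
(conv 10×3 → pool → conv 1×2 → pool → FC) is shipped for the parameter
comparison and as a float training sanity check.

Float training is plain SGD with momentum 0.9, batch size 21,
cross-entropy loss, initial learning rate 0.01 divided by 10 on a
validation-loss plateau (patience 10 epochs, 80/20 stratified split)
down to a floor of 1e-4; training stops once the rate sits at the floor
and a further patience window passes without improvement (cap 150
epochs).  The forward/backward pass is hand-derived vectorized numpy —
the network has a few hundred weights, so a framework would add nothing
but a dependency; gradients are verified against central differences in
the test suite.  Initialization is Kaiming-uniform (fan-in), biases at
zero.  Because SGD on this small non-convex surface occasionally lands
in a visibly poor optimum (final validation loss orders of magnitude
above sibling runs), the evaluation harness trains 3 independently
seeded restarts per fold and keeps the lowest-validation-loss one;
selection uses only training-side signal, and everything is
deterministic given the run seed.

## Quantization (SF-KL)

Weights: per layer, sf = 127 / max|P| and QP = round(P·sf), rounding
half away from zero, clamped to [−128, 127].  The 127 numerator keeps
the max-magnitude weight exactly representable in signed 8 bits; 128
and 255 variants exist behind a config switch, where the clamp becomes
load-bearing.  Optional biases are quantized with their layer's weight
scale — deliberately naive (see below).

Inputs: each sensor row is mean-normalized,
x' = (x − μ)/(max − min) ∈ [−1, 1], then floored onto a signed 8-bit
grid, Qx = clamp(floor(x'·127), −128, 127).  Floor (not round) matches
the shift-only datapath and is part of the contract.

Activations: between stages, a wide accumulator Y is reduced to 8 bits
purely by right-shift with saturation — QY = clamp(floor(Y/2^N), lo, hi)
— fused with ReLU for conv layers (negative Y → 0, output in [0, 127]).
The only free parameter per layer is the shift N.  SF-KL chooses it by
propagating a 21-sample calibration set (3 per class) through the float
network and the integer network in parallel; the integer path uses the
exponents already fixed for earlier layers (the deployment datapath).
For each candidate N from 0 to bit_length(max|Y|) − 7 (so at least one
saturation-free shift is always searched; readings of the search-range
bound differ by one in the source material, and this one is safe by
construction), the divergence

    KL(N) = Σ_{x > ε} x · log( x / (max(QY, ½)·2^N) )

is summed over calibration samples and the argmin N taken, ties to the
smaller N.  Two numerical choices matter here.  First, the integer
output is de-shifted by 2^N so every candidate is compared on the
common accumulator scale.  Second, an entry floored to zero stands for
anything in [0, 2^N); representing it by half an LSB keeps the penalty
continuous with the flooring-error model.  (An absolute ε-floor instead
puts a ~log(1/ε) cliff under every floored-out entry, which drags the
argmin one shift toward saturation; on the default dataset that single
detail costs about 8 points of 5-fold int8 accuracy.)  ε = 1e-10 only
excludes zero float entries (0·log 0 = 0).  A literal variant that
compares against the raw 8-bit integers is available behind a flag for
comparison.  The FC layer is calibrated with the signed
saturate-floor (no ReLU fusion — it would destroy negative logits),
although at inference the FC output is never requantized.

## Integer engine

All stages are plain integer arithmetic with declared two's-complement
accumulator widths — 20 bits for the depthwise stage, 22 for pointwise
and FC — enforced at run time (`error` raises, `saturate` clips).

The 1×3 depthwise convolution runs through the Winograd F(2,3) minimal
filtering transform: per tile of 4 inputs, input transform
[d0−d2, d1+d2, d2−d1, d1−d3], 4 elementwise products, inverse transform
[m0+m1+m2, m1−m2−m3] yields 2 outputs.  The kernel transform G contains
halves, so kernels are stored pre-transformed as 2·G·g (integral for
integer taps) and the compensating >>1 is folded into the inverse
transform; the tile sums are even by construction, so the shift is
exact and the Winograd path is bit-identical to direct convolution
(verified exhaustively over int4 and on 10⁴ random int8 cases).  The
doubled intermediates transiently use one extra bit inside a tile.  The
1×2 depthwise kernels of the second separable layer do not fit F(2,3)
and run direct convolution.  An odd trailing output position is
computed directly.

The pointwise stage is an integer matrix product per time step (the
hardware's multiplier array + adder tree); pooling is pairwise max with
stride 2, an odd trailing element is dropped (118→59 and 58→29 follow
from this).  The FC stage consumes its 290 inputs as 58 chunks of 1×5,
accumulating sequentially with a width check after every chunk —
algebraically identical to one dot product.  The 7 final logits are
compared at full 22-bit precision (the hardware max unit); no softmax
is needed for argmax, and ties break to the lowest class index.

The requantizer is implemented as the hardware would: sign bit → 0;
any bit above position N+6 set → 127; else the bit slice Y[N+6:N].
Equivalence with clamp(floor(max(Y,0)/2^N), 0, 127) is verified
exhaustively for 12-bit words and by sampling at 20/22 bits.

The 8-bit-bias engine quantizes each layer's bias with that layer's
weight scale and adds it raw to the accumulator.  This is intentionally
the naive datapath: the accumulator carries the product of input and
weight scales while the bias carries the weight scale alone, so the
added bias is off by orders of magnitude — effectively the biased-
trained network runs with its biases missing, and accuracy collapses.
The shipped configuration therefore trains without biases, which costs
nothing measurable in float accuracy here.

Storage accounting reports two conventions for the int8 conv weights:
162 plain kernel weights (1,296 bits) or 172 stored words when the 1×3
depthwise kernels are kept pre-transformed for Winograd (4 values per
3-tap kernel; 1,376 bits).  Hardware reports of ~200 stored words do
not match either enumeration; the discrepancy is left open rather than
forced.

## Synthetic data

No public deposit of the original 7-class Chinese-herbal-medicine
PEN3 recordings exists, so the package generates data with the
statistical structure the model assumes.  Per sensor i, class c and
sample: response(t) = j·(1 + (A[c,i]−1)(1 − e^{−t/τ_i}))·(1+ε_m) + ε_a,
clipped at 0 — first-order approach from the clean-air baseline 1.0
(G/G0 ratio convention) to a class-specific plateau A[c,i].  Defaults:
7 classes × 100 samples, A drawn once from LogNormal(0, 0.4) with a
fixed internal seed and shipped as a constant (so "the default dataset"
is stable across versions), per-sensor τ fixed in 5–40 s, multiplicative
and additive noise SD 0.02, per-sample lognormal amplitude jitter
SD 0.10 (headspace-concentration variation; mean-range normalization
removes most of it, as on the real instrument).  The generator emulates
rise-to-plateau kinetics and per-sensor selectivity only; it does not
model sensor drift, humidity/temperature effects, the flushing and
pre-sampling phases, or fluctuation-enhanced noise structure — so
passing tests demonstrate correctness of the pipeline and the relative
behavior of float vs int8 engines under realistic-shaped inputs, not
field performance on real herbs.

## Evaluation protocol and expected numbers

Stratified 5-fold cross-validation; per fold the float nets are trained
on the training split, SF-KL calibration draws its 3 samples per class
from the training split only (no leakage), and engines are scored on
the held-out fold.  On the default dataset (seed 0) the float model
reaches ~1.00 mean accuracy, the int8 no-bias engine is within a
fraction of a percentage point of it (gap ~0.3 pp; the published
hardware analogue lost 0.43 pp), and the int8-with-bias engine
collapses by ~30 pp.  The synthetic task is easier than the original
herbal dataset (which sat near 0.94), so absolute accuracies are not
comparable — orderings and gaps are the meaningful quantities.  A full
run (accounting, exactness sweeps, 5-fold CV of three engines) takes a
few minutes on one CPU core.

## Known limitations

- Per-layer symmetric weight scales: a single outlier weight coarsens
  the whole layer's grid (per-channel scales are out of scope).
- The calibration set cannot see test-set activation tails; a shift
  that is saturation-free on 21 samples may clip rare test peaks.
- Elementwise KL weights distortion by activation magnitude, not by
  decision relevance; near-flat KL-vs-N curves can pick a neighbor of
  the accuracy-optimal shift.
- The accumulator-width guarantee (20/22/22, overflow=error) is
  empirical for the shipped pipeline, asserted at run time, not proved.
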
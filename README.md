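# oinose

Odor identification for 10-sensor e-nose arrays with a depthwise-separable
CNN, post-training int8 quantization via a saturation-flooring
KL-divergence scale search (SF-KL), and a bit-accurate integer inference
engine that emulates a shift-only FPGA datapath.

## What this is for

An electronic nose pairs a metal-oxide gas-sensor array (here, the
10-channel PEN3 roster W1C…W3S) with a pattern-recognition model.  Running
the model *on* the sampling hardware — a small FPGA rather than a host PC —
requires an architecture with very few weights and arithmetic with no
floating point and no multipliers in the requantization path.  This package
provides the full software side of that design:

- **Model.**  A depthwise-separable 1-D CNN over 10×120 sensor time series:
  DWC 1×3 → PWC 10→6 → pool → DWC 1×2 → PWC 6→10 → pool → FC 290→7.
  Factoring each standard convolution into a per-channel and a 1×1
  cross-channel stage cuts the convolutional weight count from 316 (a
  same-footprint standard CNN, with biases) to 162; for a separable pair
  with C_inter = C_in the weight-count ratio is 1/C_out + 1/(W_K·H_K).
- **Quantization.**  Weights: per-layer sf_i = 127/max|P_i|,
  QP = round(P·sf).  Activations: each layer's wide accumulator Y is cut to
  8 bits by pure shift-with-saturation, QY_N = clamp(floor(Y/2^N), ·), and
  the per-layer exponent N is chosen by minimizing the KL divergence
  between float activations and their saturated-floored integer
  counterparts over a 21-sample calibration set (3 per class).
- **Integer engine.**  Bit-accurate emulation of the hardware blocks:
  Winograd F(2,3) depthwise convolution (bit-identical to direct
  convolution by construction), pointwise adder-tree products, 1×5-chunked
  FC accumulation, ReLU-fused bit-slice requantization, fixed accumulator
  widths (20/22/22 bits) with overflow checking, argmax at full logit
  precision.
- **Data.**  No public deposit of the original 7-class herbal-medicine
  recordings exists, so a synthetic generator emulates PEN3-like
  first-order sensor kinetics with class-specific sensitivity patterns;
  everything downstream is testable end to end without any download.

See `docs/methods.md` for the model, the calibration objective, and the
generator's assumptions and limitations.

## Worked example

```sh
oinose simulate --out herbs.csv --n-per-class 30 --seed 7
oinose train --data herbs.csv --out model --seed 7 --no-bias
oinose calibrate --model model --data herbs.csv --out int8 --seed 7
oinose infer --model int8 --input herbs.csv --engine int8 \
       --report-agreement --float-model model
```

The train step prints `{"epochs": 150, "final_loss": 0.0004,
"train_accuracy": 1.0}` — the no-bias float net fits the 210-sample
simulated set perfectly.  Calibration prints the chosen per-layer shift
exponents, e.g. `{"dwc1": 7, "pwc1": 7, "dwc2": 8, "pwc2": 7, "fc": 11}`:
each layer's accumulator is right-shifted by that many bits (scale factor
1/2^N) to fit 8 bits.  The infer step reports `"accuracy": 1.0,
"agreement_with_float": 1.0` — on this easy set the int8 engine reproduces
every float argmax.  `oinose evaluate --data herbs.csv` runs stratified
5-fold cross-validation of the float, int8-no-bias and int8-with-bias
engines and prints a per-fold table; `oinose report-params` prints the
parameter/memory accounting (316 vs 162 weights; 10,112 vs 1,296 bits).

The same functionality is available as a library:

```python
import oinose

dataset = oinose.generate_dataset(oinose.SynthConfig(seed=0))
report = oinose.kfold_evaluate(dataset, k=5, seed=0)
print(oinose.report(report, "text"))
```

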
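"""Post-training int8 quantization with saturation-flooring KL calibration (SF-KL).

Two pieces make a trained float network runnable on a shift-only integer
datapath:

1. **Weight quantization** — per layer, the max-magnitude weight M is
   mapped to full signed 8-bit scale: sf = 127 / M, QP = round(P * sf)
   (half away from zero).  Dequantization error is at most half an LSB.

2. **Activation-scale calibration** — the output of every non-pooling
   layer is reduced from its wide accumulator to 8 bits by a pure
   right-shift with saturation (no multiplier), so the only free choice
   per layer is the shift amount N (scale factor 1/2^N).  SF-KL picks N
   by propagating a small calibration set (3 samples per class) through
   the float network and the integer network in parallel and choosing,
   per layer, the N whose saturated-and-floored integer output diverges
   least — in the KL sense — from the float activation.  Integer outputs
   are de-shifted (multiplied by 2^N) before the comparison so every
   candidate N is measured on a common scale; equal-KL ties go to the
   smaller N (finer resolution).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

KL_EPS = 1e-10


class DegenerateScaleError(ValueError):
    """A layer's weights are all zero; no scale factor exists."""


# ---------------------------------------------------------------------------
# Weight quantization


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class WeightQuantResult:
    """Per-layer quantized weights with their scale factors."""

    max_abs: dict[str, float]                # M per layer
    scale: dict[str, float]                  # sf per layer
    q_weights: dict[str, np.ndarray]         # int8-ranged integers, shapes of P
    q_biases: dict[str, np.ndarray] = field(default_factory=dict)
    scale_convention: int = 127

    def dequantized(self, name: str) -> np.ndarray:
        return self.q_weights[name] / self.scale[name]


def quantize_weights(layers: dict[str, np.ndarray],
                     biases: dict[str, np.ndarray] | None = None,
                     scale_convention: int = 127,
                     rounding: str = "half_away") -> WeightQuantResult:
    """Linear 8-bit weight quantization, one scale per layer.

    ``scale_convention`` selects the numerator of sf = numerator / M;
    127 (default) guarantees round(M * sf) stays inside signed 8 bits,
    128 and 255 reproduce alternative readings of the same scheme (the
    clamp then becomes load-bearing).  ``biases``, when given, are
    quantized with their layer's *weight* scale — the convention whose
    accuracy cost the evaluation harness quantifies.
    """
    if scale_convention not in (127, 128, 255):
        raise ValueError("scale_convention must be one of 127, 128, 255")
    if rounding not in ("half_away", "banker"):
        raise ValueError("rounding must be 'half_away' or 'banker'")
    round_fn = _round_half_away if rounding == "half_away" else np.round

    max_abs: dict[str, float] = {}
    scale: dict[str, float] = {}
    qw: dict[str, np.ndarray] = {}
    qb: dict[str, np.ndarray] = {}
    for name, p in layers.items():
        p = np.asarray(p, dtype=float)
        m = float(np.max(np.abs(p)))
        if m == 0.0:
            raise DegenerateScaleError(f"layer {name!r} has all-zero weights")
        sf = scale_convention / m
        q = np.clip(round_fn(p * sf), -128, 127).astype(np.int64)
        max_abs[name] = m
        scale[name] = sf
        qw[name] = q
        if biases and name in biases:
            qb[name] = np.clip(round_fn(np.asarray(biases[name], dtype=float) * sf),
                               -128, 127).astype(np.int64)
    return WeightQuantResult(max_abs=max_abs, scale=scale, q_weights=qw,
                             q_biases=qb, scale_convention=scale_convention)


# ---------------------------------------------------------------------------
# Saturation-flooring requantization


def saturate_floor(y, n: int):
    """Signed 8-bit requantization: clamp(floor(y / 2^n), -128, 127).

    Accepts scalars or arrays; ``n`` is the power-of-two shift (N >= 0).
    """
    if n < 0:
        raise ValueError("shift exponent N must be >= 0")
    scaled = np.floor_divide(np.asarray(y), 2 ** n) if np.issubdtype(
        np.asarray(y).dtype, np.integer) else np.floor(np.asarray(y) / 2 ** n)
    out = np.clip(scaled, -128, 127).astype(np.int64)
    return out if out.ndim else int(out)


def requant_bitslice(y, n: int, n_bits: int):
    """ReLU-fused bit-sliced requantization of a width-``n_bits`` accumulator.

    Implemented as the hardware would: if the sign bit is set the output
    is 0 (ReLU); if any bit above position N+6 is set the 7-bit slice
    overflows and saturates to 127; otherwise the output is the bit
    slice Y[N+6:N].  This is provably clamp(floor(max(Y,0)/2^N), 0, 127).
    """
    if n < 0:
        raise ValueError("shift exponent N must be >= 0")
    if n + 7 > n_bits - 1:
        raise ValueError(f"N={n} too large for a {n_bits}-bit accumulator")
    y_arr = np.asarray(y, dtype=np.int64)
    lo, hi = -(1 << (n_bits - 1)), (1 << (n_bits - 1)) - 1
    if np.any(y_arr < lo) or np.any(y_arr > hi):
        raise OverflowError(f"value outside {n_bits}-bit two's-complement range")
    neg = y_arr < 0                       # sign bit of the two's-complement word
    overflow = (y_arr >> (n + 7)) != 0    # any bit above position N+6 (y >= 0 here)
    sliced = (y_arr >> n) & 0x7F          # the slice Y[N+6:N]
    out = np.where(neg, 0, np.where(overflow, 127, sliced)).astype(np.int64)
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# KL divergence and per-layer exponent search


def kl_divergence(x_float: np.ndarray, qy: np.ndarray, n: int,
                  literal: bool = False) -> float:
    """Divergence of the float activation from its requantized counterpart.

    sum over entries with x > eps of x * log(x / ref), with
    ref = max(qy, 1/2) * 2^n: the integer output is de-shifted by 2^n so
    all candidate exponents are compared on the accumulator scale, and
    an entry floored to zero — which stands for anything in [0, 2^n) —
    is represented by half an LSB rather than by an arbitrarily small
    constant (an absolute floor would put a ~log(1/eps) cliff under
    every floored-out entry and systematically drag the argmin toward
    saturating shifts).  Entries where the float activation is <= eps
    contribute nothing (0 * log 0 == 0 convention); negative float
    entries are likewise excluded, which only matters for the signed
    (FC) layer.  ``literal=True`` compares against the raw 8-bit
    integers without the de-shift instead.
    """
    x = np.asarray(x_float, dtype=float).ravel()
    q = np.asarray(qy, dtype=float).ravel()
    if x.shape != q.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {q.shape}")
    mask = x > KL_EPS
    if not np.any(mask):
        return 0.0
    if literal:
        ref = np.maximum(q[mask], KL_EPS)
    else:
        ref = np.maximum(q[mask], 0.5) * float(2 ** n)
    return float(np.sum(x[mask] * np.log(x[mask] / ref)))


def max_search_exponent(max_abs_output: int) -> int:
    """Largest N worth searching for a layer whose peak |output| is given.

    One past the point where the full range fits in 7 bits after the
    shift, i.e. bit_length(max|Y|) - 7, clamped at 0 — so the search
    always includes at least one saturation-free candidate.
    """
    return max(0, int(max_abs_output).bit_length() - 7)


def choose_exponent(float_acts: list[np.ndarray], wide_acts: list[np.ndarray],
                    n_bits: int, signed: bool = False) -> tuple[int, dict[int, float]]:
    """Search N = 0..max for one layer; returns (argmin N, KL-vs-N table).

    ``float_acts`` / ``wide_acts`` are per-calibration-sample activations
    from the float and integer paths.  ``signed`` selects plain
    saturate-floor (used for the FC logits, where a fused ReLU would
    destroy negative values) over the ReLU-fused bit slice.
    """
    peak = max((int(np.max(np.abs(w))) if w.size else 0) for w in wide_acts)
    if peak == 0:
        warnings.warn("layer output identically zero across calibration set; N=0")
        return 0, {0: 0.0}
    n_max = max_search_exponent(peak)
    n_max = min(n_max, n_bits - 8)  # bit-slice admissibility: N+7 <= n_bits-1
    table: dict[int, float] = {}
    for n in range(n_max + 1):
        total = 0.0
        for xf, yw in zip(float_acts, wide_acts):
            qy = saturate_floor(yw, n) if signed else requant_bitslice(yw, n, n_bits)
            total += kl_divergence(xf, qy, n)
        table[n] = total
    best = min(table, key=lambda n: (table[n], n))
    return best, table


@dataclass
class CalibrationResult:
    """Chosen shift exponent per layer, with the KL curves that justified them."""

    exponents: dict[str, int]
    kl_tables: dict[str, dict[int, float]]
    n_samples: int

    def scale(self, name: str) -> float:
        return 1.0 / 2 ** self.exponents[name]

    def to_json(self) -> str:
        return json.dumps({
            "n_samples": self.n_samples,
            "layers": {
                name: {
                    "N": self.exponents[name],
                    "sf": self.scale(name),
                    "kl_table": {str(k): v for k, v in self.kl_tables[name].items()},
                }
                for name in self.exponents
            },
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResult":
        obj = json.loads(text)
        exponents = {k: int(v["N"]) for k, v in obj["layers"].items()}
        tables = {k: {int(n): kl for n, kl in v["kl_table"].items()}
                  for k, v in obj["layers"].items()}
        return cls(exponents=exponents, kl_tables=tables,
                   n_samples=int(obj["n_samples"]))


def calibrate(float_net, wq: WeightQuantResult, normalized_samples,
              quantized_samples, fixed_point=None, use_bias: bool = False) -> CalibrationResult:
    """Run the SF-KL search over every non-pooling layer, in network order.

    The float path propagates each calibration sample through the float
    network; the integer path propagates its quantized counterpart
    through the integer engine, requantizing each layer with the
    exponents already chosen for the layers before it (the deployment
    datapath), and exposing the wide pre-shift accumulator of the layer
    under calibration.
    """
    from .int_engine import FixedPointConfig, layer_plan, run_int_layers

    if len(normalized_samples) == 0:
        raise ValueError("empty calibration set")
    if len(normalized_samples) != len(quantized_samples):
        raise ValueError("calibration sample lists must align")
    cfg = fixed_point or FixedPointConfig()

    plan = layer_plan(float_net.spec)
    float_acts = [float_net.forward_activations(ns.values[None, :, :])
                  for ns in normalized_samples]
    int_states = [np.asarray(qs.values, dtype=np.int64) for qs in quantized_samples]

    exponents: dict[str, int] = {}
    tables: dict[str, dict[int, float]] = {}
    for step in plan:
        if step.kind == "maxpool":
            int_states = [run_int_layers([step], s, wq, exponents, cfg, use_bias)
                          for s in int_states]
            continue
        wide = [run_int_layers([step], s, wq, exponents, cfg, use_bias,
                               stop_before_requant=True) for s in int_states]
        floats = [acts[step.name][0] for acts in float_acts]
        n_bits = cfg.acc_bits(step.kind)
        signed = step.kind == "fully_connected"
        best, table = choose_exponent(floats, wide, n_bits, signed=signed)
        exponents[step.name] = best
        tables[step.name] = table
        if signed:
            int_states = [saturate_floor(w, best) for w in wide]
        else:
            int_states = [requant_bitslice(w, best, n_bits) for w in wide]
    return CalibrationResult(exponents=exponents, kl_tables=tables,
                             n_samples=len(normalized_samples))
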
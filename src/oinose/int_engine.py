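"""Bit-accurate integer inference engine emulating the FPGA datapath.

The pipeline mirrors the hardware block structure: a Winograd depthwise
convolution unit (WDCU), a pointwise convolution unit (PCU) with adder
tree, max-pooling, a fully connected unit (FCU) that consumes its input
in 1x5 chunks with a sequential accumulator, and a shift-only
requantization (fused with ReLU) between stages.  Every stage works on
plain integers with a declared two's-complement accumulator width
(20 bits for the depthwise stage, 22 for pointwise and FC), so results
are bit-reproducible across platforms.

The F(2,3) Winograd transform contains halves in its kernel matrix G;
kernels are pre-transformed as 2*G*g (integral for integer g) and the
compensating right-shift by one is folded into the inverse transform,
which keeps the whole path exact: the Winograd output is identical, bit
for bit, to direct convolution.  The doubled intermediates transiently
use one extra bit inside the tile; the declared width is enforced on the
stage's outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sfkl import CalibrationResult, WeightQuantResult, requant_bitslice, saturate_floor
from .specs import NetworkSpec


class AccumulatorOverflowError(OverflowError):
    """An intermediate sum left the declared accumulator width."""


@dataclass(frozen=True)
class FixedPointConfig:
    """Stage accumulator widths and what to do when a sum escapes them."""

    dwc_acc_bits: int = 20
    pwc_acc_bits: int = 22
    fc_acc_bits: int = 22
    overflow: str = "error"   # or "saturate"

    def __post_init__(self) -> None:
        for name in ("dwc_acc_bits", "pwc_acc_bits", "fc_acc_bits"):
            if getattr(self, name) < 16:
                raise ValueError(f"{name} must be >= 16")
        if self.overflow not in ("error", "saturate"):
            raise ValueError("overflow policy must be 'error' or 'saturate'")

    def acc_bits(self, kind: str) -> int:
        return {
            "depthwise_conv": self.dwc_acc_bits,
            "pointwise_conv": self.pwc_acc_bits,
            "fully_connected": self.fc_acc_bits,
        }[kind]


@dataclass(frozen=True)
class QuantizedTensor:
    """Integer tensor with its power-of-two scale exponent and declared width."""

    values: np.ndarray
    scale_exponent: int = 0
    bits: int = 8
    signed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        lo = -(1 << (self.bits - 1)) if self.signed else 0
        hi = (1 << (self.bits - 1)) - 1 if self.signed else (1 << self.bits) - 1
        if v.size and (v.min() < lo or v.max() > hi):
            raise ValueError(f"values outside {self.bits}-bit range [{lo}, {hi}]")
        object.__setattr__(self, "values", v)


def _enforce_width(y: np.ndarray, bits: int, policy: str, stage: str) -> np.ndarray:
    lo, hi = -(1 << (bits - 1)), (1 << (bits - 1)) - 1
    if y.size == 0 or (y.min() >= lo and y.max() <= hi):
        return y
    if policy == "error":
        raise AccumulatorOverflowError(
            f"{stage}: value outside {bits}-bit range (min {y.min()}, max {y.max()})"
        )
    return np.clip(y, lo, hi)


# ---------------------------------------------------------------------------
# Stage primitives


@dataclass(frozen=True)
class WinogradKernel:
    """Pre-transformed 3-tap kernel U = 2*G*g (stored doubled to stay integral)."""

    u: np.ndarray  # length 4

    @classmethod
    def from_taps(cls, kernel) -> "WinogradKernel":
        k = np.asarray(kernel, dtype=np.int64)
        if k.shape != (3,):
            raise ValueError("Winograd F(2,3) needs a 3-tap kernel")
        return cls(u=np.array([2 * k[0], k[0] + k[1] + k[2],
                               k[0] - k[1] + k[2], 2 * k[2]], dtype=np.int64))


def direct_dwconv(x, kernel) -> np.ndarray:
    """Naive valid cross-correlation of one channel; the engine's oracle twin."""
    x = np.asarray(x, dtype=np.int64)
    k = np.asarray(kernel, dtype=np.int64)
    n_out = x.size - k.size + 1
    if n_out <= 0:
        raise ValueError("sequence shorter than kernel")
    out = np.zeros(n_out, dtype=np.int64)
    for j in range(k.size):
        out += k[j] * x[j:j + n_out]
    return out


def winograd_f23_dwconv(channel_seq, kernel) -> np.ndarray:
    """F(2,3) Winograd valid convolution of one channel with a 3-tap kernel.

    Tiles of 4 inputs yield 2 outputs via the transforms
    input  [d0-d2, d1+d2, d2-d1, d1-d3],
    output [m0+m1+m2, m1-m2-m3],
    using the doubled kernel transform and a folded >>1 (exact: the tile
    sums are even by construction).  Bit-identical to direct convolution.
    """
    x = np.asarray(channel_seq, dtype=np.int64)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D sequence of length >= 4")
    u = WinogradKernel.from_taps(kernel).u
    n_out = x.size - 2
    n_tiles = n_out // 2
    idx = 2 * np.arange(n_tiles)
    d0, d1, d2, d3 = x[idx], x[idx + 1], x[idx + 2], x[idx + 3]
    m0 = (d0 - d2) * u[0]
    m1 = (d1 + d2) * u[1]
    m2 = (d2 - d1) * u[2]
    m3 = (d1 - d3) * u[3]
    out = np.empty(n_out, dtype=np.int64)
    out[0:2 * n_tiles:2] = (m0 + m1 + m2) >> 1
    out[1:2 * n_tiles:2] = (m1 - m2 - m3) >> 1
    if n_out % 2:  # odd tail: one output computed directly
        t = n_out - 1
        k = np.asarray(kernel, dtype=np.int64)
        out[t] = k[0] * x[t] + k[1] * x[t + 1] + k[2] * x[t + 2]
    return out


def pointwise_conv(x, w) -> np.ndarray:
    """1x1 cross-channel convolution: per position an integer dot product."""
    x = np.asarray(x, dtype=np.int64)
    w = np.asarray(w, dtype=np.int64)
    if x.ndim != 2 or w.ndim != 2 or w.shape[1] != x.shape[0]:
        raise ValueError(f"shape mismatch: x {x.shape}, w {w.shape}")
    return w @ x


def maxpool_1x2(x) -> np.ndarray:
    """Pairwise max with stride 2 along the last axis; odd tail dropped."""
    x = np.asarray(x)
    t = (x.shape[-1] // 2) * 2
    pairs = x[..., :t].reshape(*x.shape[:-1], t // 2, 2)
    return pairs.max(axis=-1)


def fc_chunked(x, w, chunk: int = 5, acc_bits: int | None = None,
               policy: str = "error") -> np.ndarray:
    """Fully connected layer computed over 1x``chunk`` input slices.

    Each output neuron accumulates 58 (for 290 inputs) chunk dot
    products sequentially; the running accumulator is width-checked
    after every chunk.  Algebraically identical to one full dot product.
    """
    x = np.asarray(x, dtype=np.int64).ravel()
    w = np.asarray(w, dtype=np.int64)
    if w.ndim != 2 or w.shape[1] != x.size:
        raise ValueError(f"shape mismatch: x {x.shape}, w {w.shape}")
    if x.size % chunk != 0:
        raise ValueError(f"input length {x.size} not divisible into 1x{chunk} chunks")
    acc = np.zeros(w.shape[0], dtype=np.int64)
    for start in range(0, x.size, chunk):
        acc = acc + w[:, start:start + chunk] @ x[start:start + chunk]
        if acc_bits is not None:
            acc = _enforce_width(acc, acc_bits, policy, "FCU accumulator")
    return acc


# ---------------------------------------------------------------------------
# Full pipeline


def layer_plan(spec: NetworkSpec):
    """The engine's stage sequence: every layer except the softmax."""
    return [ls for ls in spec.layers if ls.kind != "softmax"]


def _layer_weights(wq: WeightQuantResult, name: str, kind: str) -> np.ndarray:
    try:
        w = wq.q_weights[name]
    except KeyError:
        raise ValueError(f"quantized weights missing for layer {name!r}") from None
    if kind == "pointwise_conv" and w.ndim == 3 and w.shape[2] == 1:
        w = w[:, :, 0]
    return np.asarray(w, dtype=np.int64)


def run_int_layers(steps, state: np.ndarray, wq: WeightQuantResult,
                   exponents: dict[str, int], cfg: FixedPointConfig,
                   use_bias: bool = False,
                   stop_before_requant: bool = False) -> np.ndarray:
    """Propagate an integer activation through ``steps``.

    ``state`` is (C, W) between stages (the quantized input for the first
    stage).  With ``stop_before_requant`` the wide accumulator of the
    final step is returned instead of its 8-bit requantized output —
    this is what SF-KL calibration scores.
    """
    state = np.asarray(state, dtype=np.int64)
    for i, step in enumerate(steps):
        last = i == len(steps) - 1
        if step.kind == "maxpool":
            state = maxpool_1x2(state)
            continue
        if step.kind == "depthwise_conv":
            w = _layer_weights(wq, step.name, step.kind)
            conv = winograd_f23_dwconv if w.shape[1] == 3 else direct_dwconv
            wide = np.stack([conv(state[c], w[c]) for c in range(state.shape[0])])
            bits = cfg.dwc_acc_bits
        elif step.kind == "pointwise_conv":
            w = _layer_weights(wq, step.name, step.kind)
            wide = pointwise_conv(state, w)
            bits = cfg.pwc_acc_bits
        elif step.kind == "fully_connected":
            w = _layer_weights(wq, step.name, step.kind)
            wide = fc_chunked(state.ravel(), w, chunk=5,
                              acc_bits=cfg.fc_acc_bits, policy=cfg.overflow)
            bits = cfg.fc_acc_bits
        else:
            raise ValueError(f"integer engine does not implement {step.kind!r}")

        if use_bias and step.name in wq.q_biases:
            qb = np.asarray(wq.q_biases[step.name], dtype=np.int64)
            wide = wide + (qb[:, None] if wide.ndim == 2 else qb)
        wide = _enforce_width(wide, bits, cfg.overflow, step.name)

        if last and stop_before_requant:
            return wide
        if step.kind == "fully_connected":
            state = wide  # logits stay at full accumulator precision
        else:
            try:
                n = exponents[step.name]
            except KeyError:
                raise ValueError(f"no calibrated scale for layer {step.name!r}") from None
            state = requant_bitslice(wide, n, bits)
            assert state.min() >= 0 and state.max() <= 127
    return state


def forward_int8(sample, wq: WeightQuantResult, cal: CalibrationResult,
                 cfg: FixedPointConfig | None = None,
                 use_bias: bool = False,
                 spec: NetworkSpec | None = None) -> tuple[int, np.ndarray]:
    """Integer forward pass: class index (argmax of raw logits) and logits.

    The FC output is compared at full accumulator precision — the
    hardware max unit — so no softmax and no final requantization are
    involved; argmax ties break to the lowest class index.
    """
    cfg = cfg or FixedPointConfig()
    if spec is None:
        from .specs import oidscnn_spec
        spec = oidscnn_spec(bias=use_bias)
    values = sample.values if hasattr(sample, "values") else sample
    QuantizedTensor(values, bits=8, signed=True)  # input range assertion
    logits = run_int_layers(layer_plan(spec), np.asarray(values, dtype=np.int64),
                            wq, cal.exponents, cfg, use_bias=use_bias)
    return int(np.argmax(logits)), logits
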
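"""Per-sensor mean normalization, int8 input quantization, channel reshape.

Each sensor row x_i is mean-normalized into [-1, 1],

    x'_{i,j} = (x_{i,j} - mu_i) / (max(x_i) - min(x_i)),

then linearly quantized to a signed 8-bit grid with floor rounding,

    Qx = clamp(floor(x' * 127), -128, 127).

Floor (toward -inf), not round, is used deliberately: it matches the
shift-based hardware datapath the integer engine emulates, and the
resulting asymmetry is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

INT8_MIN, INT8_MAX = -128, 127


class DegenerateInputError(ValueError):
    """A sensor row is constant: normalization is undefined."""


@dataclass(frozen=True)
class NormalizedSample:
    """Mean-normalized recording with per-sensor stats retained for audit."""

    values: np.ndarray      # (n_sensors, n_timepoints), entries in [-1, 1]
    mean: np.ndarray        # mu_i per sensor
    row_max: np.ndarray
    row_min: np.ndarray
    label: int = -1
    sample_id: str = ""


@dataclass(frozen=True)
class QuantizedSample:
    """Signed 8-bit quantized recording."""

    values: np.ndarray      # int8-ranged integers
    label: int = -1
    sample_id: str = ""


def mean_normalize(values: np.ndarray, label: int = -1, sample_id: str = "") -> NormalizedSample:
    """Normalize each sensor row by its mean and range.

    ``values`` may be a raw matrix or a SensorRecording-like object with
    ``.values``/``.label``/``.sample_id``.
    """
    if hasattr(values, "values") and not isinstance(values, np.ndarray):
        rec = values
        values, label, sample_id = rec.values, rec.label, rec.sample_id
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D sensor matrix, got shape {x.shape}")
    mu = x.mean(axis=1)
    hi = x.max(axis=1)
    lo = x.min(axis=1)
    rng = hi - lo
    flat = np.nonzero(rng == 0)[0]
    if flat.size:
        raise DegenerateInputError(
            f"sensor row(s) {flat.tolist()} are constant (max == min); "
            "mean normalization is undefined"
        )
    normalized = (x - mu[:, None]) / rng[:, None]
    return NormalizedSample(
        values=normalized, mean=mu, row_max=hi, row_min=lo,
        label=label, sample_id=sample_id,
    )


def quantize_input(ns: NormalizedSample, scale_bits: int = 7) -> QuantizedSample:
    """Quantize a normalized sample to signed 8 bits: floor(x' * (2^scale_bits - 1)).

    The default scale 2^7 - 1 = 127 keeps all of [-1, 1] inside the signed
    8-bit range; the clamp is defensive.
    """
    x = ns.values if isinstance(ns, NormalizedSample) else np.asarray(ns, dtype=float)
    if np.any(x < -1.0) or np.any(x > 1.0):
        raise ValueError("normalized values must lie in [-1, 1]")
    scale = 2 ** scale_bits - 1
    q = np.clip(np.floor(x * scale), INT8_MIN, INT8_MAX).astype(np.int64)
    label = getattr(ns, "label", -1)
    sample_id = getattr(ns, "sample_id", "")
    return QuantizedSample(values=q, label=label, sample_id=sample_id)


def reshape_for_dwc(sample: np.ndarray) -> np.ndarray:
    """Reshape a (w, h) sensor matrix to (channels=w, height=1, width=h).

    The w sensor rows become w independent channels, so the depthwise
    stage convolves each sensor's time series with its own 1-D kernel.
    """
    x = np.asarray(sample)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {x.shape}")
    return x[:, None, :]


def inverse_reshape(tensor: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_for_dwc`."""
    t = np.asarray(tensor)
    if t.ndim != 3 or t.shape[1] != 1:
        raise ValueError(f"expected shape (channels, 1, width), got {t.shape}")
    return t[:, 0, :]
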
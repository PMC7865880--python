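"""Synthetic PEN3-style e-nose dataset generation and CSV I/O.

A PEN3 instrument reports, for each of 10 metal-oxide (MOS) sensors, a
dimensionless response ratio (conductance over clean-air baseline, G/G0)
sampled once per second over a 120 s measurement window.  Exposure to an
odor drives each sensor from its baseline of 1.0 toward a compound- and
sensor-specific plateau; the approach is well described by first-order
kinetics.  The generator emulates exactly that structure:

    x_i(t) = jitter * (1 + (A[c,i] - 1) * (1 - exp(-t / tau_i)))
             * (1 + eps_mult(t)) + eps_add(t),        clipped at 0

per sensor ``i``, odor class ``c`` and sample, with a per-sample
log-normal amplitude jitter (headspace concentration varies between
repetitions), multiplicative sensor noise and additive acquisition noise.
Classes differ only through their steady-state sensitivity pattern
``A[c, :]`` across the 10 sensors, which is what makes the array an
electronic nose.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: PEN3 sensor names, in instrument order.
SENSOR_NAMES = ("W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S")

N_SENSORS = 10
N_TIMEPOINTS = 120

_CSV_META_COLUMNS = ("sample_id", "label", "t")


def _default_sensitivity_matrix(n_classes: int = 7) -> np.ndarray:
    """Per-class steady-state amplitude per sensor, 7 x 10.

    Drawn once from LogNormal(0, 0.4) with a fixed internal seed and
    shipped as the package's stable default, so "the default dataset"
    means the same recordings in every version.
    """
    rng = np.random.default_rng(20210832)
    return rng.lognormal(mean=0.0, sigma=0.4, size=(n_classes, N_SENSORS))


def _default_rise_tau() -> np.ndarray:
    """Per-sensor rise time constants (s), fixed draw in 5-40 s.

    MOS sensors equilibrate on tens of seconds; heterogeneous taus give
    each channel a distinct transient, as real arrays show.
    """
    rng = np.random.default_rng(832)
    return rng.uniform(5.0, 40.0, size=N_SENSORS)


@dataclass(frozen=True)
class SensorRecording:
    """One odor measurement: 10 sensors x 120 time points plus its label."""

    values: np.ndarray
    label: int
    sample_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"recording must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"sample {self.sample_id!r} contains non-finite values")
        if np.any(values < 0):
            raise ValueError(f"sample {self.sample_id!r} contains negative responses")
        object.__setattr__(self, "values", values)

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the 700-sample, 7-class study design."""

    n_classes: int = 7
    n_per_class: int = 100
    sensitivity_matrix: np.ndarray = field(default_factory=_default_sensitivity_matrix)
    rise_tau: np.ndarray = field(default_factory=_default_rise_tau)
    noise_sd_add: float = 0.02
    noise_sd_mult: float = 0.02
    amplitude_jitter_sd: float = 0.10
    n_timepoints: int = N_TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        self.sensitivity_matrix = np.asarray(self.sensitivity_matrix, dtype=float)
        self.rise_tau = np.asarray(self.rise_tau, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.sensitivity_matrix.shape != (self.n_classes, N_SENSORS):
            raise ValueError(
                "sensitivity_matrix must have shape "
                f"({self.n_classes}, {N_SENSORS}), got {self.sensitivity_matrix.shape}"
            )
        if np.any(self.sensitivity_matrix <= 0):
            raise ValueError("sensitivity_matrix entries must be positive")
        rows = self.sensitivity_matrix
        for a in range(self.n_classes):
            for b in range(a + 1, self.n_classes):
                if np.array_equal(rows[a], rows[b]):
                    raise ValueError(f"sensitivity rows {a} and {b} are identical")
        if self.rise_tau.shape != (N_SENSORS,):
            raise ValueError(f"rise_tau must have shape ({N_SENSORS},)")
        if np.any(self.rise_tau <= 0):
            raise ValueError("all rise_tau must be > 0")
        for name in ("noise_sd_add", "noise_sd_mult", "amplitude_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


def noiseless_response(config: SynthConfig, label: int) -> np.ndarray:
    """Jitter- and noise-free response curves for one class, 10 x T.

    Time runs 1..T seconds (1 s sample interval; the first stored point
    is one interval into the exposure).
    """
    t = np.arange(1, config.n_timepoints + 1, dtype=float)
    amp = config.sensitivity_matrix[label][:, None]  # (10, 1)
    tau = config.rise_tau[:, None]
    return 1.0 + (amp - 1.0) * (1.0 - np.exp(-t[None, :] / tau))


def generate_dataset(config: SynthConfig) -> list[SensorRecording]:
    """Generate ``n_classes * n_per_class`` recordings, deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    recordings: list[SensorRecording] = []
    for label in range(config.n_classes):
        clean = noiseless_response(config, label)  # (10, T)
        for s in range(config.n_per_class):
            jitter = rng.lognormal(mean=0.0, sigma=config.amplitude_jitter_sd) \
                if config.amplitude_jitter_sd > 0 else 1.0
            mult = rng.normal(0.0, config.noise_sd_mult, size=clean.shape) \
                if config.noise_sd_mult > 0 else 0.0
            add = rng.normal(0.0, config.noise_sd_add, size=clean.shape) \
                if config.noise_sd_add > 0 else 0.0
            values = jitter * clean * (1.0 + mult) + add
            np.clip(values, 0.0, None, out=values)
            recordings.append(
                SensorRecording(values=values, label=label, sample_id=f"c{label}s{s:03d}")
            )
    return recordings


def steady_state_features(dataset: list[SensorRecording], tail: int = 20) -> np.ndarray:
    """Mean response over the last ``tail`` time points, one row per sample."""
    return np.stack([rec.values[:, -tail:].mean(axis=1) for rec in dataset])


def labels(dataset: list[SensorRecording]) -> np.ndarray:
    return np.array([rec.label for rec in dataset], dtype=int)


# ---------------------------------------------------------------------------
# CSV I/O: long format, one row per (sample, time point).


def write_csv(dataset: list[SensorRecording], path) -> None:
    """Write recordings to CSV at full float precision (round-trip exact)."""
    if not dataset:
        raise ValueError("dataset must be non-empty")
    frames = []
    for rec in dataset:
        df = pd.DataFrame(rec.values.T, columns=list(SENSOR_NAMES[: rec.n_sensors]))
        df.insert(0, "t", np.arange(1, rec.n_timepoints + 1))
        df.insert(0, "label", rec.label)
        df.insert(0, "sample_id", rec.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


class DatasetFormatError(ValueError):
    """Raised when a CSV dataset violates the recording format."""


def read_csv(path, n_timepoints: int = N_TIMEPOINTS) -> list[SensorRecording]:
    """Read recordings written by :func:`write_csv`; columns matched by name."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (*_CSV_META_COLUMNS, *SENSOR_NAMES) if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing columns: {missing}")
    recordings = []
    # groupby(sort=False) preserves file order of samples
    for sample_id, group in df.groupby("sample_id", sort=False):
        group = group.sort_values("t")
        if len(group) != n_timepoints:
            raise DatasetFormatError(
                f"sample {sample_id!r} has {len(group)} time points, "
                f"expected {n_timepoints}"
            )
        lab = group["label"].unique()
        if len(lab) != 1:
            raise DatasetFormatError(f"sample {sample_id!r} has inconsistent labels")
        values = group[list(SENSOR_NAMES)].to_numpy(dtype=float).T
        recordings.append(
            SensorRecording(values=values, label=int(lab[0]), sample_id=str(sample_id))
        )
    if not recordings:
        raise DatasetFormatError("file contains no samples")
    return recordings
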
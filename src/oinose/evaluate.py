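"""Stratified k-fold evaluation of the float and int8 engines.

Per fold: a float network is trained on the training split, its weights
are quantized, SF-KL calibration runs on 3 training-split samples per
class (21 for the 7-class default — never from the held-out fold), and
the requested engines are scored on the held-out fold.

Engines:

* ``float``       — the trained float network (with biases).
* ``int8_nobias`` — a float network trained *without* biases, quantized
                    and run on the integer pipeline.  The deployment
                    configuration.
* ``int8_bias``   — the biased float network with weights *and* biases
                    quantized to 8 bits (biases on the weight scale) and
                    the biases added raw to the integer accumulators.
                    This is the naive datapath whose scale mismatch the
                    harness quantifies; it is expected to collapse.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import int_engine, network, preprocessing, sfkl
from .specs import oidscnn_spec
from .synth import SensorRecording

ENGINES = ("float", "int8_nobias", "int8_bias")


@dataclass
class CVReport:
    """Per-fold and mean accuracies per engine, with the run's provenance."""

    fold_accuracies: dict[str, list[float]]
    mean_accuracy: dict[str, float]
    agreement_with_float: dict[str, float] = field(default_factory=dict)
    confusion: dict[str, list[list[int]]] = field(default_factory=dict)
    k: int = 5
    seed: int = 0
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for engine, folds in self.fold_accuracies.items():
            if not all(0.0 <= a <= 1.0 for a in folds):
                raise ValueError(f"accuracies out of [0, 1] for {engine}")
            mean = float(np.mean(folds))
            if abs(mean - self.mean_accuracy[engine]) > 1e-12:
                raise ValueError(f"stored mean inconsistent for {engine}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CVReport":
        return cls(**json.loads(text))


def preprocess_dataset(dataset: list[SensorRecording]):
    """Normalize and quantize every recording; returns (norm, quant, labels)."""
    normalized = [preprocessing.mean_normalize(rec) for rec in dataset]
    quantized = [preprocessing.quantize_input(ns) for ns in normalized]
    y = np.array([rec.label for rec in dataset], dtype=int)
    return normalized, quantized, y


def _pick_calibration(y_train: np.ndarray, per_class: int,
                      rng: np.random.Generator) -> np.ndarray:
    chosen = []
    for cls in np.unique(y_train):
        idx = np.nonzero(y_train == cls)[0]
        chosen.extend(rng.choice(idx, size=min(per_class, len(idx)), replace=False))
    return np.array(sorted(chosen))


def _quantize_model(net: network.FloatNetwork, with_bias: bool) -> sfkl.WeightQuantResult:
    weights = net.weights_by_name()
    layers = {name: entry["w"] for name, entry in weights.items()}
    biases = {name: entry["b"] for name, entry in weights.items()
              if with_bias and "b" in entry}
    return sfkl.quantize_weights(layers, biases=biases or None)


def kfold_evaluate(dataset: list[SensorRecording], k: int = 5,
                   engines: tuple[str, ...] = ENGINES, seed: int = 0,
                   train_cfg: network.TrainConfig | None = None,
                   calibration_per_class: int = 3,
                   n_restarts: int = 3,
                   fixed_point: int_engine.FixedPointConfig | None = None) -> CVReport:
    """Stratified k-fold cross-validation of the requested engines."""
    if k < 2:
        raise ValueError("k must be >= 2")
    unknown = set(engines) - set(ENGINES)
    if unknown:
        raise ValueError(f"unknown engines: {sorted(unknown)}")
    normalized, quantized, y = preprocess_dataset(dataset)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k samples, got {counts.min()}")
    x = np.stack([ns.values for ns in normalized])

    cfg = fixed_point or int_engine.FixedPointConfig()
    n_classes = int(y.max()) + 1
    folds: dict[str, list[float]] = {e: [] for e in engines}
    agreement: dict[str, list[float]] = {e: [] for e in engines if e != "float"}
    confusion = {e: np.zeros((n_classes, n_classes), dtype=int) for e in engines}

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_i, (tr, te) in enumerate(skf.split(x, y)):
        fold_seed = seed * 1000 + fold_i
        tcfg_b = _fold_cfg(train_cfg, fold_seed)
        rng = np.random.default_rng(fold_seed + 500)
        cal_idx = tr[_pick_calibration(y[tr], calibration_per_class, rng)]

        need_biased = "float" in engines or "int8_bias" in engines
        net_b = None
        if need_biased:
            net_b, _ = network.train_with_restarts(oidscnn_spec(bias=True),
                                                   x[tr], y[tr], tcfg_b,
                                                   n_restarts=n_restarts)
        float_pred = net_b.predict(x[te]) if net_b is not None else None

        for engine in engines:
            if engine == "float":
                pred = float_pred
            else:
                if engine == "int8_nobias":
                    net, _ = network.train_with_restarts(
                        oidscnn_spec(bias=False), x[tr], y[tr],
                        _fold_cfg(train_cfg, fold_seed), n_restarts=n_restarts)
                    wq = _quantize_model(net, with_bias=False)
                    use_bias = False
                else:
                    net = net_b
                    wq = _quantize_model(net, with_bias=True)
                    use_bias = True
                cal = sfkl.calibrate(net, wq,
                                     [normalized[i] for i in cal_idx],
                                     [quantized[i] for i in cal_idx],
                                     fixed_point=cfg, use_bias=use_bias)
                pred = np.array([
                    int_engine.forward_int8(quantized[i], wq, cal, cfg,
                                            use_bias=use_bias, spec=net.spec)[0]
                    for i in te
                ])
                if float_pred is not None:
                    agreement[engine].append(float(np.mean(pred == float_pred)))
            folds[engine].append(float(np.mean(pred == y[te])))
            np.add.at(confusion[engine], (y[te], pred), 1)

    return CVReport(
        fold_accuracies={e: folds[e] for e in engines},
        mean_accuracy={e: float(np.mean(folds[e])) for e in engines},
        agreement_with_float={e: float(np.mean(v)) for e, v in agreement.items() if v},
        confusion={e: confusion[e].tolist() for e in engines},
        k=k, seed=seed,
        config={"calibration_per_class": calibration_per_class,
                "fixed_point": cfg.__dict__},
    )


def _fold_cfg(base: network.TrainConfig | None, fold_seed: int) -> network.TrainConfig:
    base = base or network.TrainConfig()
    return network.TrainConfig(**{**base.__dict__, "seed": fold_seed})


def report(cvr: CVReport, fmt: str = "text") -> str:
    """Render a cross-validation report as text, JSON or CSV."""
    if fmt == "json":
        return cvr.to_json()
    if fmt == "csv":
        buf = io.StringIO()
        folds = ",".join(f"fold{i + 1}" for i in range(cvr.k))
        buf.write(f"engine,{folds},average\n")
        for engine, accs in cvr.fold_accuracies.items():
            cells = ",".join(f"{a:.4f}" for a in accs)
            buf.write(f"{engine},{cells},{cvr.mean_accuracy[engine]:.4f}\n")
        return buf.getvalue()
    if fmt == "text":
        lines = [f"{cvr.k}-fold cross-validation (seed {cvr.seed})"]
        header = "engine       " + " ".join(f"fold{i + 1:<2}" for i in range(cvr.k)) \
                 + "  average"
        lines.append(header)
        for engine, accs in cvr.fold_accuracies.items():
            cells = " ".join(f"{a:.4f}" for a in accs)
            lines.append(f"{engine:<12} {cells}  {cvr.mean_accuracy[engine]:.4f}")
        for engine, agr in cvr.agreement_with_float.items():
            lines.append(f"{engine} argmax agreement with float: {agr:.4f}")
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}")
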
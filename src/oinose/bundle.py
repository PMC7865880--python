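"""On-disk model containers.

Float models: a directory with ``weights.npz`` (one array per layer
weight/bias, keyed ``<layer>.w`` / ``<layer>.b``) and ``manifest.json``
recording the architecture name, bias flag and per-array shapes/dtypes.

Quantized bundles add ``qweights.npz`` (integer weights, plus quantized
biases when present), the per-layer scale factors, the calibrated shift
exponents and the accumulator widths, all listed in the manifest so the
integer engine can run without the float model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .int_engine import FixedPointConfig
from .network import FloatNetwork
from .sfkl import CalibrationResult, WeightQuantResult
from .specs import NetworkSpec, cnn_baseline_spec, oidscnn_spec

_ARCHITECTURES = {"OI-DSCNN": oidscnn_spec, "CNN": cnn_baseline_spec}


def _spec_from_manifest(manifest: dict) -> NetworkSpec:
    name = manifest["architecture"]
    if name not in _ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}")
    return _ARCHITECTURES[name](bias=manifest["bias"])


def save_float_model(net: FloatNetwork, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = net.weights_by_name()
    arrays = {}
    layers = {}
    for name, entry in weights.items():
        arrays[f"{name}.w"] = entry["w"]
        layers[name] = {"w": {"shape": list(entry["w"].shape), "dtype": "float64"}}
        if "b" in entry:
            arrays[f"{name}.b"] = entry["b"]
            layers[name]["b"] = {"shape": list(entry["b"].shape), "dtype": "float64"}
    np.savez(path / "weights.npz", **arrays)
    manifest = {
        "kind": "float",
        "architecture": net.spec.name,
        "bias": any("b" in e for e in weights.values()),
        "layers": layers,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_float_model(path) -> FloatNetwork:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("kind") != "float":
        raise ValueError(f"{path} is not a float model directory")
    net = FloatNetwork(_spec_from_manifest(manifest), seed=0)
    with np.load(path / "weights.npz") as data:
        weights: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            name, part = key.rsplit(".", 1)
            weights.setdefault(name, {})[part] = data[key]
    net.set_weights(weights)
    return net


def save_quantized_bundle(wq: WeightQuantResult, cal: CalibrationResult,
                          cfg: FixedPointConfig, path,
                          architecture: str = "OI-DSCNN",
                          use_bias: bool = False) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {f"{name}.w": w for name, w in wq.q_weights.items()}
    arrays.update({f"{name}.b": b for name, b in wq.q_biases.items()})
    np.savez(path / "qweights.npz", **arrays)
    manifest = {
        "kind": "int8",
        "architecture": architecture,
        "bias": use_bias,
        "scale_convention": wq.scale_convention,
        "layers": {
            name: {
                "shape": list(wq.q_weights[name].shape),
                "max_abs": wq.max_abs[name],
                "weight_scale": wq.scale[name],
                "shift_exponent": cal.exponents.get(name),
            }
            for name in wq.q_weights
        },
        "accumulator_bits": {"dwc": cfg.dwc_acc_bits, "pwc": cfg.pwc_acc_bits,
                             "fc": cfg.fc_acc_bits},
        "overflow": cfg.overflow,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (path / "calibration.json").write_text(cal.to_json())


def load_quantized_bundle(path):
    """Returns (spec, WeightQuantResult, CalibrationResult, FixedPointConfig, use_bias)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("kind") != "int8":
        raise ValueError(f"{path} is not a quantized bundle")
    with np.load(path / "qweights.npz") as data:
        qw = {}
        qb = {}
        for key in data.files:
            name, part = key.rsplit(".", 1)
            (qw if part == "w" else qb)[name] = data[key].astype(np.int64)
    wq = WeightQuantResult(
        max_abs={n: m["max_abs"] for n, m in manifest["layers"].items()},
        scale={n: m["weight_scale"] for n, m in manifest["layers"].items()},
        q_weights=qw, q_biases=qb,
        scale_convention=manifest["scale_convention"],
    )
    cal = CalibrationResult.from_json((path / "calibration.json").read_text())
    bits = manifest["accumulator_bits"]
    cfg = FixedPointConfig(dwc_acc_bits=bits["dwc"], pwc_acc_bits=bits["pwc"],
                           fc_acc_bits=bits["fc"], overflow=manifest["overflow"])
    spec = _spec_from_manifest(manifest)
    return spec, wq, cal, cfg, manifest["bias"]
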
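"""Floating-point forward/backward pass and the SGD training harness.

The networks here are small enough (a few hundred weights) that a
vectorized numpy implementation with hand-derived gradients is both fast
and fully deterministic; there is no framework dependency to pin.

Activations are (batch, channels, width) arrays.  A standard convolution
whose kernel height equals the input height (the baseline net's 10x3
first layer on the 10x120 sensor image) collapses the height axis and is
realised as a 1-D convolution with ``H * C`` input channels — the weight
layout and arithmetic are identical.

Training follows the published recipe: SGD with momentum 0.9, batch
size 21, cross-entropy loss, initial learning rate 0.01 divided by 10 on
validation-loss plateau down to a floor of 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .specs import NetworkSpec, LayerSpec


# ---------------------------------------------------------------------------
# Layers

class Layer:
    """Base layer: forward caches what backward needs; params exposes weights."""

    name = ""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(weight, gradient) pairs updated by the optimizer."""
        return []


class DepthwiseConv1D(Layer):
    """Per-channel valid 1-D cross-correlation with a k-tap kernel."""

    def __init__(self, channels: int, k: int, bias: bool, rng: np.random.Generator,
                 name: str = ""):
        bound = np.sqrt(6.0 / k)
        self.w = rng.uniform(-bound, bound, size=(channels, k))
        self.b = np.zeros(channels) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros(channels) if bias else None
        self.k = k
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        t_out = x.shape[2] - self.k + 1
        out = np.zeros((x.shape[0], x.shape[1], t_out))
        for k in range(self.k):
            out += x[:, :, k:k + t_out] * self.w[None, :, k, None]
        if self.b is not None:
            out += self.b[None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        t_out = grad.shape[2]
        gx = np.zeros_like(x)
        for k in range(self.k):
            self.gw[:, k] = np.sum(grad * x[:, :, k:k + t_out], axis=(0, 2))
            gx[:, :, k:k + t_out] += grad * self.w[None, :, k, None]
        if self.gb is not None:
            self.gb[:] = grad.sum(axis=(0, 2))
        return gx

    def params(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class Conv1D(Layer):
    """Standard valid 1-D cross-correlation, c_in -> c_out channels.

    With k == 1 this is the pointwise (1x1) convolution.
    """

    def __init__(self, c_in: int, c_out: int, k: int, bias: bool,
                 rng: np.random.Generator, name: str = ""):
        bound = np.sqrt(6.0 / (c_in * k))
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in, k))
        self.b = np.zeros(c_out) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros(c_out) if bias else None
        self.k = k
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        t_out = x.shape[2] - self.k + 1
        out = np.zeros((x.shape[0], self.w.shape[0], t_out))
        for k in range(self.k):
            out += np.einsum("oc,bct->bot", self.w[:, :, k], x[:, :, k:k + t_out])
        if self.b is not None:
            out += self.b[None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        t_out = grad.shape[2]
        gx = np.zeros_like(x)
        for k in range(self.k):
            self.gw[:, :, k] = np.einsum("bot,bct->oc", grad, x[:, :, k:k + t_out])
            gx[:, :, k:k + t_out] += np.einsum("oc,bot->bct", self.w[:, :, k], grad)
        if self.gb is not None:
            self.gb[:] = grad.sum(axis=(0, 2))
        return gx

    def params(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class ReLU(Layer):
    def __init__(self, name: str = ""):
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1x2(Layer):
    """Pairwise max, stride 2; an odd trailing element is dropped."""

    def __init__(self, name: str = ""):
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        t = (x.shape[2] // 2) * 2
        pairs = x[:, :, :t].reshape(x.shape[0], x.shape[1], t // 2, 2)
        self._arg = pairs.argmax(axis=3)
        self._in_shape = x.shape
        return pairs.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape)
        t2 = grad.shape[2]
        gpairs = gx[:, :, : t2 * 2].reshape(grad.shape[0], grad.shape[1], t2, 2)
        np.put_along_axis(gpairs, self._arg[..., None], grad[..., None], axis=3)
        return gx


class Flatten(Layer):
    """(B, C, W) -> (B, C*W), channel-major; the integer engine flattens identically."""

    def __init__(self, name: str = ""):
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, bias: bool, rng: np.random.Generator,
                 name: str = ""):
        bound = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.b = np.zeros(n_out) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros(n_out) if bias else None
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.w.T
        if self.b is not None:
            out += self.b
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw[:] = grad.T @ self._x
        if self.gb is not None:
            self.gb[:] = grad.sum(axis=0)
        return grad @ self.w

    def params(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


# ---------------------------------------------------------------------------
# Network

class FloatNetwork:
    """Sequential float network built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        shape = spec.input_shape  # (H, W, C)
        for ls in spec.layers:
            self._append_layer(ls, shape, rng)
            shape = ls.output_shape(shape)

    def _append_layer(self, ls: LayerSpec, shape, rng) -> None:
        h = shape[0] if len(shape) == 3 else 1
        if ls.kind == "depthwise_conv":
            self.layers.append(DepthwiseConv1D(ls.c_in, ls.kernel[1], ls.bias, rng, ls.name))
            self.layers.append(ReLU(name=ls.name + "_relu"))
        elif ls.kind == "pointwise_conv":
            self.layers.append(Conv1D(ls.c_in, ls.c_out, 1, ls.bias, rng, ls.name))
            self.layers.append(ReLU(name=ls.name + "_relu"))
        elif ls.kind == "standard_conv":
            hk = ls.kernel[0]
            if hk != 1 and hk != h:
                raise ValueError(
                    f"standard_conv kernel height {hk} must be 1 or the full "
                    f"input height {h}"
                )
            self.layers.append(Conv1D(ls.c_in * hk, ls.c_out, ls.kernel[1],
                                      ls.bias, rng, ls.name))
            self.layers.append(ReLU(name=ls.name + "_relu"))
        elif ls.kind == "maxpool":
            self.layers.append(MaxPool1x2(name=ls.name))
        elif ls.kind == "fully_connected":
            self.layers.append(Flatten(name=ls.name + "_flatten"))
            self.layers.append(Dense(ls.c_in, ls.c_out, ls.bias, rng, ls.name))
        # softmax is folded into the loss / argmax prediction

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (B, C, W) batch."""
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_activations(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Named post-ReLU conv activations and FC logits, for calibration."""
        acts: dict[str, np.ndarray] = {}
        pending = None
        for layer in self.layers:
            x = layer.forward(x)
            if isinstance(layer, (DepthwiseConv1D, Conv1D)):
                pending = layer.name
            elif isinstance(layer, ReLU) and pending is not None:
                acts[pending] = x
                pending = None
            elif isinstance(layer, Dense):
                acts[layer.name] = x
        acts["__logits__"] = x
        return acts

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        return logits.argmax(axis=1)

    def weights_by_name(self) -> dict[str, dict[str, np.ndarray]]:
        """{layer name: {"w": ..., "b": ... (if present)}} for trainable layers."""
        out: dict[str, dict[str, np.ndarray]] = {}
        for layer in self.layers:
            if isinstance(layer, (DepthwiseConv1D, Conv1D, Dense)):
                entry = {"w": layer.w}
                if layer.b is not None:
                    entry["b"] = layer.b
                out[layer.name] = entry
        return out

    def set_weights(self, weights: dict[str, dict[str, np.ndarray]]) -> None:
        for layer in self.layers:
            if isinstance(layer, (DepthwiseConv1D, Conv1D, Dense)) and layer.name in weights:
                entry = weights[layer.name]
                layer.w[:] = entry["w"]
                if layer.b is not None and "b" in entry:
                    layer.b[:] = entry["b"]


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-300)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


# ---------------------------------------------------------------------------
# Training

@dataclass
class TrainConfig:
    batch_size: int = 21
    momentum: float = 0.9
    lr_init: float = 0.01
    lr_floor: float = 0.0001
    lr_decay_factor: float = 10.0
    plateau_patience: int = 10
    max_epochs: int = 150
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.plateau_patience, self.max_epochs) <= 0:
            raise ValueError("batch_size, plateau_patience, max_epochs must be positive")
        if not (0 < self.lr_floor < self.lr_init):
            raise ValueError("need 0 < lr_floor < lr_init")
        if self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must exceed 1")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainResult:
    loss_curve: list[float] = field(default_factory=list)
    val_loss_curve: list[float] = field(default_factory=list)
    lr_curve: list[float] = field(default_factory=list)
    n_epochs: int = 0


def _stratified_split(y: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_val = int(round(len(idx) * val_fraction))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train(net: FloatNetwork, x: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None) -> TrainResult:
    """SGD-with-momentum training, deterministic given ``cfg.seed``.

    The learning rate is divided by ``lr_decay_factor`` when the
    validation loss has not improved for ``plateau_patience`` epochs and
    never drops below ``lr_floor``; training stops early once the rate
    sits at the floor and a further full patience window passes without
    improvement.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(y, dtype=int)
    if len(x) == 0:
        raise ValueError("empty training set")
    n_classes = net.spec.output_shape()[-1]
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")

    rng = np.random.default_rng(cfg.seed)
    if cfg.val_fraction > 0:
        tr_idx, val_idx = _stratified_split(y, cfg.val_fraction, rng)
        if len(val_idx) == 0:
            tr_idx = np.arange(len(y))
            val_idx = tr_idx
    else:
        tr_idx = np.arange(len(y))
        val_idx = tr_idx
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    params = net.params()
    velocity = [np.zeros_like(w) for w, _ in params]
    lr = cfg.lr_init
    best_val = np.inf
    stale = 0
    result = TrainResult()

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            logits = net.forward(x_tr[batch])
            loss, grad = softmax_cross_entropy(logits, y_tr[batch])
            net.backward(grad)
            for (w, g), v in zip(params, velocity):
                v *= cfg.momentum
                v -= lr * g
                w += v
            epoch_loss += loss
            n_batches += 1

        val_loss, _ = softmax_cross_entropy(net.forward(x_val), y_val)
        result.loss_curve.append(epoch_loss / max(n_batches, 1))
        result.val_loss_curve.append(float(val_loss))
        result.lr_curve.append(lr)
        result.n_epochs = epoch + 1

        if val_loss < best_val - 1e-6:
            best_val = float(val_loss)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.plateau_patience:
                if lr / cfg.lr_decay_factor >= cfg.lr_floor:
                    lr = max(lr / cfg.lr_decay_factor, cfg.lr_floor)
                    stale = 0
                else:
                    break  # at the floor and still flat: converged
    return result


def train_with_restarts(spec: NetworkSpec, x: np.ndarray, y: np.ndarray,
                        cfg: TrainConfig | None = None,
                        n_restarts: int = 3) -> tuple[FloatNetwork, TrainResult]:
    """Train ``n_restarts`` independently initialized networks and keep the
    one with the lowest final validation loss.

    SGD on this loss surface occasionally settles in a visibly poor
    optimum (validation loss orders of magnitude above sibling runs);
    restart selection on the validation signal screens those out without
    ever looking at held-out data.  Deterministic given ``cfg.seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    cfg = cfg or TrainConfig()
    best: tuple[float, FloatNetwork, TrainResult] | None = None
    for r in range(n_restarts):
        seed_r = cfg.seed + 10_000 * r
        net = FloatNetwork(spec, seed=seed_r)
        cfg_r = TrainConfig(**{**cfg.__dict__, "seed": seed_r})
        result = train(net, x, y, cfg_r)
        val = result.val_loss_curve[-1]
        if best is None or val < best[0]:
            best = (val, net, result)
    return best[1], best[2]


def accuracy(net: FloatNetwork, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(net.predict(x) == np.asarray(y)))
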
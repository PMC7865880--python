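"""Declarative network architectures and parameter/memory accounting.

Two fixed architectures are shipped:

* ``oidscnn_spec()`` — the depthwise-separable odor-identification net:
  DWC 1x3 (10 ch) -> PWC 10->6 -> pool 1x2 -> DWC 1x2 (6 ch) ->
  PWC 6->10 -> pool 1x2 -> FC 290->7 -> softmax.
* ``cnn_baseline_spec()`` — the standard-convolution reference net with
  the same footprint: conv 10x3 (1->6) on the 10x120 image -> pool ->
  conv 1x2 (6->10) -> pool -> FC 290->7 -> softmax.

All convolutions are valid (no padding) with stride 1; pooling is 1x2
with stride 2.  Activation shapes are (H, W, C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

CONV_KINDS = ("depthwise_conv", "pointwise_conv", "standard_conv")
KINDS = (*CONV_KINDS, "maxpool", "fully_connected", "softmax")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    kernel: tuple[int, int] = (1, 1)    # (H_K, W_K)
    c_in: int = 0
    c_out: int = 0
    stride: int = 1
    bias: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in CONV_KINDS and self.stride != 1:
            raise ValueError("convolution stride must be 1")
        if self.kind == "maxpool" and self.stride != 2:
            raise ValueError("max-pooling stride must be 2")
        if self.kind == "depthwise_conv" and self.c_out != self.c_in:
            raise ValueError("depthwise layers must have c_out == c_in")
        if self.kind == "pointwise_conv" and self.kernel != (1, 1):
            raise ValueError("pointwise layers use a 1x1 kernel")

    def output_shape(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        """Shape produced from input ``shape`` ((H, W, C), or (F,) after FC)."""
        if self.kind == "softmax":
            return shape
        if self.kind == "fully_connected":
            n = 1
            for d in shape:
                n *= d
            if n != self.c_in:
                raise ValueError(
                    f"FC layer {self.name!r} expects {self.c_in} inputs, "
                    f"got shape {shape} ({n})"
                )
            return (self.c_out,)
        if len(shape) != 3:
            raise ValueError(f"layer {self.name!r} expects (H, W, C), got {shape}")
        h, w, c = shape
        hk, wk = self.kernel
        if self.kind == "maxpool":
            return (h // hk if hk > 1 else h, w // wk, c)
        if h < hk or w < wk:
            raise ValueError(f"input {shape} smaller than kernel {self.kernel}")
        if self.kind == "depthwise_conv":
            if c != self.c_in:
                raise ValueError(f"layer {self.name!r}: channel mismatch {c} != {self.c_in}")
            return (h - hk + 1, w - wk + 1, c)
        if self.kind == "pointwise_conv":
            if c != self.c_in:
                raise ValueError(f"layer {self.name!r}: channel mismatch {c} != {self.c_in}")
            return (h, w, self.c_out)
        # standard_conv
        if c != self.c_in:
            raise ValueError(f"layer {self.name!r}: channel mismatch {c} != {self.c_in}")
        return (h - hk + 1, w - wk + 1, self.c_out)

    def parameter_count(self, include_bias: bool = True) -> int:
        hk, wk = self.kernel
        if self.kind == "depthwise_conv":
            n = hk * wk * self.c_in
            b = self.c_in
        elif self.kind == "pointwise_conv":
            n = self.c_in * self.c_out
            b = self.c_out
        elif self.kind == "standard_conv":
            n = hk * wk * self.c_in * self.c_out
            b = self.c_out
        elif self.kind == "fully_connected":
            n = self.c_in * self.c_out
            b = self.c_out
        else:
            return 0
        return n + (b if include_bias and self.bias else 0)


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    input_shape: tuple[int, int, int]
    layers: tuple[LayerSpec, ...] = field(default_factory=tuple)

    def shape_chain(self) -> list[tuple[int, ...]]:
        """Input shape of every layer, ending with the final output shape."""
        shapes = [self.input_shape]
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
            shapes.append(shape)
        return shapes

    def output_shape(self) -> tuple[int, ...]:
        return self.shape_chain()[-1]

    def validate(self) -> None:
        self.shape_chain()


def oidscnn_spec(bias: bool = True) -> NetworkSpec:
    """The depthwise-separable odor-identification architecture."""
    return NetworkSpec(
        name="OI-DSCNN",
        input_shape=(1, 120, 10),
        layers=(
            LayerSpec("depthwise_conv", (1, 3), 10, 10, bias=bias, name="dwc1"),
            LayerSpec("pointwise_conv", (1, 1), 10, 6, bias=bias, name="pwc1"),
            LayerSpec("maxpool", (1, 2), stride=2, name="pool1"),
            LayerSpec("depthwise_conv", (1, 2), 6, 6, bias=bias, name="dwc2"),
            LayerSpec("pointwise_conv", (1, 1), 6, 10, bias=bias, name="pwc2"),
            LayerSpec("maxpool", (1, 2), stride=2, name="pool2"),
            LayerSpec("fully_connected", c_in=290, c_out=7, bias=bias, name="fc"),
            LayerSpec("softmax", name="softmax"),
        ),
    )


def cnn_baseline_spec(bias: bool = True) -> NetworkSpec:
    """Standard-convolution reference architecture of matching footprint."""
    return NetworkSpec(
        name="CNN",
        input_shape=(10, 120, 1),
        layers=(
            LayerSpec("standard_conv", (10, 3), 1, 6, bias=bias, name="conv1"),
            LayerSpec("maxpool", (1, 2), stride=2, name="pool1"),
            LayerSpec("standard_conv", (1, 2), 6, 10, bias=bias, name="conv2"),
            LayerSpec("maxpool", (1, 2), stride=2, name="pool2"),
            LayerSpec("fully_connected", c_in=290, c_out=7, bias=bias, name="fc"),
            LayerSpec("softmax", name="softmax"),
        ),
    )


def count_parameters(spec: NetworkSpec, include_bias: bool = True,
                     conv_only: bool = False) -> int:
    """Exact closed-form parameter count.

    ``conv_only`` restricts the count to convolutional layers, the
    quantity usually quoted when comparing separable vs standard nets
    (both published counts — 316 with biases for the standard net, 162
    kernel weights for the separable net — are conv-only).
    """
    total = 0
    for layer in spec.layers:
        if conv_only and layer.kind not in CONV_KINDS:
            continue
        total += layer.parameter_count(include_bias=include_bias)
    return total


def memory_bits(param_count: int, bits_per_param: int) -> int:
    """Storage footprint in bits of ``param_count`` parameters."""
    if param_count < 0 or bits_per_param <= 0:
        raise ValueError("param_count must be >= 0 and bits_per_param > 0")
    return param_count * bits_per_param


def separable_reduction_ratio(w_k: int, h_k: int, c_in: int,
                              c_inter: int, c_out: int) -> Fraction:
    """Weight-count ratio of a separable pair over the standard convolution.

    (W_K*H_K*C_inter + C_inter*C_out) / (W_K*H_K*C_in*C_out); with
    C_inter == C_in this reduces to 1/C_out + 1/(W_K*H_K), so the
    separable pair is cheaper whenever (W_K*H_K - 1)(C_out - 1) > 1.
    Returned as an exact Fraction.
    """
    if min(w_k, h_k, c_in, c_inter, c_out) <= 0:
        raise ValueError("all dimensions must be positive")
    return Fraction(w_k * h_k * c_inter + c_inter * c_out,
                    w_k * h_k * c_in * c_out)
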
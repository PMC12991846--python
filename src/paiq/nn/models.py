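"""No-reference quality-regression architectures.

Three CNNs map a single 128x128x1 grayscale reconstruction (NHWC) to one or more
scalar quality scores:

* **PAQNet** — lightweight 4-conv stack with filter counts (32, 64, 128, 256)
  and kernels (5, 3, 3, 3), each conv followed by ReLU and 2x2 max pooling,
  then two 128-unit dense layers.  2,502,273 trainable parameters for one
  output.
* **IQDCNN** — four 32-filter 5x5 conv layers with pooling, then three
  1024-unit dense layers with dropout 0.3; a deeper-headed baseline.
* **EfficientNetIQA** — an EfficientNet-B0 topology (MBConv blocks with
  squeeze-excitation) adapted to single-channel input, with a 128-unit
  regression head; randomly initialized (no pretrained weights are shipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    BatchNorm2d, Conv2d, Dropout, Flatten, GlobalAvgPool, Linear, MaxPool2x2,
    MBConv, Module, ReLU, Sequential, SiLU,
)

__all__ = ["PAQNetSpec", "IQDCNNSpec", "EffNetIQASpec", "build_model"]


@dataclass(frozen=True)
class PAQNetSpec:
    filters: tuple[int, ...] = (32, 64, 128, 256)
    kernels: tuple[int, ...] = (5, 3, 3, 3)
    dense_units: int = 128
    input_size: int = 128


@dataclass(frozen=True)
class IQDCNNSpec:
    filters: tuple[int, ...] = (32, 32, 32, 32)
    kernel: int = 5
    dense_units: int = 1024
    dropout: float = 0.3
    input_size: int = 128


@dataclass(frozen=True)
class EffNetIQASpec:
    """EfficientNet-B0 stage configuration (expand, channels, repeats, stride, kernel)."""

    stages: tuple = (
        (1, 16, 1, 1, 3),
        (6, 24, 2, 2, 3),
        (6, 40, 2, 2, 5),
        (6, 80, 3, 2, 3),
        (6, 112, 3, 1, 5),
        (6, 192, 4, 2, 5),
        (6, 320, 1, 1, 3),
    )
    stem_channels: int = 32
    head_channels: int = 1280
    dense_units: int = 128
    input_size: int = 128


class _RegressorNet(Sequential):
    """Sequential regressor exposing its final convolutional layer for Grad-CAM."""

    def __init__(self, layers, final_conv_index):
        super().__init__(*layers)
        self.final_conv_index = final_conv_index

    @property
    def final_conv_activation_layer(self):
        return self.layers[self.final_conv_index]


def _paqnet(spec: PAQNetSpec, n_outputs: int, rng) -> _RegressorNet:
    layers: list[Module] = []
    cin, side = 1, spec.input_size
    for f, k in zip(spec.filters, spec.kernels):
        layers += [Conv2d(cin, f, k, padding=k // 2, rng=rng,
                          input_grad=cin != 1), ReLU(), MaxPool2x2()]
        cin, side = f, side // 2
    final_conv_relu = len(layers) - 2  # ReLU after the last conv
    layers += [
        Flatten(),
        Linear(cin * side * side, spec.dense_units, rng=rng), ReLU(),
        Linear(spec.dense_units, spec.dense_units, rng=rng), ReLU(),
        Linear(spec.dense_units, n_outputs, rng=rng),
    ]
    return _RegressorNet(layers, final_conv_relu)


def _iqdcnn(spec: IQDCNNSpec, n_outputs: int, rng) -> _RegressorNet:
    layers: list[Module] = []
    cin, side = 1, spec.input_size
    for f in spec.filters:
        layers += [Conv2d(cin, f, spec.kernel, padding=spec.kernel // 2, rng=rng,
                          input_grad=cin != 1), ReLU(), MaxPool2x2()]
        cin, side = f, side // 2
    final_conv_relu = len(layers) - 2
    layers += [Flatten()]
    in_features = cin * side * side
    for _ in range(3):
        layers += [Linear(in_features, spec.dense_units, rng=rng), ReLU(),
                   Dropout(spec.dropout, rng=np.random.default_rng(rng.integers(2**31 - 1)))]
        in_features = spec.dense_units
    layers += [Linear(spec.dense_units, n_outputs, rng=rng)]
    return _RegressorNet(layers, final_conv_relu)


def _effnet(spec: EffNetIQASpec, n_outputs: int, rng) -> _RegressorNet:
    layers: list[Module] = [
        Conv2d(1, spec.stem_channels, 3, stride=2, padding=1, bias=False, rng=rng,
               input_grad=False),
        BatchNorm2d(spec.stem_channels), SiLU(),
    ]
    cin = spec.stem_channels
    for expand, cout, repeats, stride, kernel in spec.stages:
        for r in range(repeats):
            layers.append(MBConv(cin, cout, kernel, stride if r == 0 else 1,
                                 expand, rng=rng))
            cin = cout
    layers += [
        Conv2d(cin, spec.head_channels, 1, bias=False, rng=rng),
        BatchNorm2d(spec.head_channels),
    ]
    final_conv_bn = len(layers) - 1
    layers += [
        SiLU(),
        GlobalAvgPool(),
        Linear(spec.head_channels, spec.dense_units, rng=rng), ReLU(),
        Linear(spec.dense_units, n_outputs, rng=rng),
    ]
    net = _RegressorNet(layers, final_conv_bn)
    return net


def build_model(spec, n_outputs: int = 1, seed: int = 0) -> _RegressorNet:
    """Instantiate a randomly initialized regressor for the given architecture spec."""
    if n_outputs < 1:
        raise ValueError("n_outputs must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(spec, PAQNetSpec):
        net = _paqnet(spec, n_outputs, rng)
    elif isinstance(spec, IQDCNNSpec):
        net = _iqdcnn(spec, n_outputs, rng)
    elif isinstance(spec, EffNetIQASpec):
        net = _effnet(spec, n_outputs, rng)
    else:
        raise TypeError(f"unknown architecture spec {type(spec).__name__}")
    net.input_size = spec.input_size
    return net
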
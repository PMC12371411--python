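"""The 3D CNN binary classifier architecture.

Input layer, then one feature-extraction block per convolution stage
(Conv3D+ReLU -> MaxPool3D -> BatchNorm), then the classification block
(GlobalAvgPool3D -> Dense(ReLU) -> Dropout -> Dense(1, sigmoid)). The
reference configuration — five conv stages with 64/64/128/128/256 filters,
3x3x3 kernels, (2,2,2) pooling, a 512-unit dense layer and 30% dropout —
has 20 layers and 1,795,905 parameters; smaller configurations are used for
desk-scale training. Global average pooling makes the parameter count
independent of the input spatial size.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .layers import (BatchNorm3D, Conv3D, Dense, Dropout, GlobalAvgPool3D,
                     Input, Layer, MaxPool3D)


@dataclasses.dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, int, int] = (193, 229, 193)
    channels: int = 1
    conv_filters: tuple[int, ...] = (64, 64, 128, 128, 256)
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool_size: tuple[int, int, int] = (2, 2, 2)
    dense_units: int = 512
    dropout_rate: float = 0.30
    #: batch-norm moving-statistics momentum; short desk-scale runs need a
    #: smaller value so inference statistics converge within a few epochs
    bn_momentum: float = 0.99

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1:
            raise ValueError("need at least one convolution block")
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("filter counts must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0,1)")
        min_extent = 2 ** len(self.conv_filters)
        if any(s < min_extent for s in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} too small for "
                f"{len(self.conv_filters)} pooling halvings (need >= {min_extent})")

    @staticmethod
    def desk_scale(input_shape: tuple[int, int, int] = (32, 32, 32)) -> "CNNConfig":
        """A small configuration for CPU-scale experiments on phantom data."""
        return CNNConfig(input_shape=input_shape, conv_filters=(8, 16),
                         dense_units=32, bn_momentum=0.9)


class CNN3D:
    """A built network: an ordered layer list with forward/backward passes."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[Layer] = [Input(config.input_shape)]
        c_in = config.channels
        for f in config.conv_filters:
            layers.append(Conv3D(c_in, f, config.kernel, relu=True, rng=rng))
            layers.append(MaxPool3D())
            layers.append(BatchNorm3D(f, momentum=config.bn_momentum))
            c_in = f
        layers.append(GlobalAvgPool3D())
        layers.append(Dense(c_in, config.dense_units, activation="relu", rng=rng))
        layers.append(Dropout(config.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
        layers.append(Dense(config.dense_units, 1, activation="sigmoid", rng=rng))
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N, 1, D, H, W) volumes to per-sample probabilities (N,)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[:, None]
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = np.asarray(grad_out, dtype=np.float32)[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def trainable_params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.trainable]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.gradients]

    def state_arrays(self) -> list[np.ndarray]:
        return [s for l in self.layers for s in l.state]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.trainable_params() + self.state_arrays()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        targets = self.trainable_params() + self.state_arrays()
        if len(weights) != len(targets):
            raise ValueError("weight list length mismatch")
        for t, w in zip(targets, weights):
            t[...] = w


def build_cnn(config: CNNConfig, seed: int = 0) -> CNN3D:
    """Instantiate the network; raises if the input shape cannot survive the
    pooling depth (checked in CNNConfig)."""
    return CNN3D(config, seed=seed)


def count_parameters(config: CNNConfig) -> int:
    """Total parameter count, including the two batch-norm moving statistics
    per channel (4 per batch-normalized channel in total)."""
    model = CNN3D(config, seed=0)
    return sum(l.n_params() for l in model.layers)


def count_layers(config: CNNConfig) -> int:
    """Layer count: input + 3 per conv block (conv, pool, batch-norm) +
    global-average-pool + dense + dropout + output."""
    n_blocks = len(config.conv_filters)
    if n_blocks < 1:
        raise ValueError("need at least one convolution block")
    return 1 + 3 * n_blocks + 1 + 1 + 1 + 1
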
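"""3D densely connected convolutional classifier with optional scalar late fusion.

The network is a 3D DenseNet: a convolutional stem, four dense blocks
interleaved with compressing transition layers, adaptive average pooling, and
a classification head. In the scalar-fusion variant the pooled feature vector
is passed through a narrow linear layer, concatenated with the patient-level
RSIrs_max scalar, and mapped to the two-way output — so the imaging features
and the quantitative diffusion biomarker are fused late, at the head.

The full-size configuration follows the published channel schedule
(64 stem features, growth rate 32, blocks of 6/12/24/16 layers, compression
0.5: 64 -> 256 -> 128 -> 512 -> 256 -> 1024 -> 512 -> 1024); the ``tiny``
preset keeps the same topology at desk scale for tests and synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import ConfigurationError
from . import autograd as ag
from .autograd import Tensor
from .layers import BatchNorm3d, Conv3d, Linear, Module

__all__ = ["DenseNetConfig", "channel_trace", "DenseNet3d", "build_model"]


@dataclass(frozen=True)
class DenseNetConfig:
    in_channels: int = 3
    init_features: int = 64
    growth_rate: int = 32
    block_layers: tuple[int, int, int, int] = (6, 12, 24, 16)
    compression: float = 0.5
    out_classes: int = 2
    scalar_fusion: bool = False
    fusion_width: int = 5
    preset: str = "full"

    def validate(self) -> None:
        if not 0 < self.compression <= 1:
            raise ConfigurationError("compression must be in (0, 1]")
        if self.in_channels <= 0 or self.init_features <= 0:
            raise ConfigurationError("channel counts must be positive")
        if len(self.block_layers) != 4:
            raise ConfigurationError("expected 4 dense blocks")

    @classmethod
    def full(cls, in_channels: int = 3, scalar_fusion: bool = False) -> "DenseNetConfig":
        """Full-size configuration with the published channel schedule."""
        return cls(in_channels=in_channels, scalar_fusion=scalar_fusion, preset="full")

    @classmethod
    def tiny(cls, in_channels: int = 3, scalar_fusion: bool = False) -> "DenseNetConfig":
        return cls(
            in_channels=in_channels,
            init_features=8,
            growth_rate=4,
            block_layers=(2, 2, 2, 2),
            scalar_fusion=scalar_fusion,
            preset="tiny",
        )


def channel_trace(config: DenseNetConfig) -> tuple[int, ...]:
    """Feature-map channel counts after the stem, each block and each transition.

    Stem emits ``init_features``; a block of L layers adds L * growth_rate;
    transitions 1-3 multiply by ``compression`` (floor).
    """
    config.validate()
    trace = [config.init_features]
    ch = config.init_features
    for i, layers in enumerate(config.block_layers):
        ch += layers * config.growth_rate
        trace.append(ch)
        if i < 3:
            ch = int(np.floor(ch * config.compression))
            trace.append(ch)
    return tuple(trace)


class _DenseLayer(Module):
    def __init__(self, in_ch: int, growth: int, rng):
        super().__init__()
        self.bn = BatchNorm3d(in_ch)
        self.conv = Conv3d(in_ch, growth, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(ag.relu(self.bn(x)))
        return ag.concat([x, y], axis=1)


class _DenseBlock(Module):
    def __init__(self, layers: list[_DenseLayer]):
        super().__init__()
        self.layers = layers

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _Transition(Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.bn = BatchNorm3d(in_ch)
        self.conv = Conv3d(in_ch, out_ch, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.avgpool3d(self.conv(ag.relu(self.bn(x))))


class DenseNet3d(Module):
    """Forward accepts (batch, in_channels, x, y, z) and, when scalar fusion is
    enabled, a (batch,) scalar vector; returns per-class scores (batch, 2)."""

    def __init__(self, config: DenseNetConfig, seed: int = 0):
        super().__init__()
        config.validate()
        rng = np.random.default_rng(seed)
        self.config = config
        trace = channel_trace(config)
        self.stem_conv = Conv3d(config.in_channels, config.init_features, 3, rng=rng)
        self.stem_bn = BatchNorm3d(config.init_features)
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[_Transition] = []
        ch = config.init_features
        for i, layers in enumerate(config.block_layers):
            block = []
            for _ in range(layers):
                block.append(_DenseLayer(ch, config.growth_rate, rng))
                ch += config.growth_rate
            self.blocks.append(_DenseBlock(block))
            if i < 3:
                out_ch = int(np.floor(ch * config.compression))
                self.transitions.append(_Transition(ch, out_ch, rng))
                ch = out_ch
        self.final_bn = BatchNorm3d(ch)
        self.final_channels = ch
        assert ch == trace[-1]
        if config.scalar_fusion:
            self.fc_reduce = Linear(ch, config.fusion_width, rng=rng)
            self.fc_out = Linear(config.fusion_width + 1, config.out_classes, rng=rng)
        else:
            self.fc_out = Linear(ch, config.out_classes, rng=rng)

    def __call__(self, x: Tensor | np.ndarray, scalar: np.ndarray | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim != 5 or x.data.shape[1] != self.config.in_channels:
            raise ConfigurationError(
                f"expected input (batch, {self.config.in_channels}, x, y, z), got {x.data.shape}"
            )
        if self.config.scalar_fusion and scalar is None:
            raise ConfigurationError("scalar-fusion model requires the rsirs_max scalar batch")
        if not self.config.scalar_fusion and scalar is not None:
            raise ConfigurationError("model without scalar fusion rejects a scalar argument")

        h = ag.avgpool3d(ag.relu(self.stem_bn(self.stem_conv(x))))
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i < 3:
                h = self.transitions[i](h)
        h = ag.global_mean_pool(ag.relu(self.final_bn(h)))
        if self.config.scalar_fusion:
            reduced = self.fc_reduce(h)
            s = Tensor(np.asarray(scalar, dtype=float).reshape(-1, 1))
            h = ag.concat([reduced, s], axis=1)
        return self.fc_out(h)


def build_model(config: DenseNetConfig, seed: int = 0) -> DenseNet3d:
    return DenseNet3d(config, seed=seed)
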
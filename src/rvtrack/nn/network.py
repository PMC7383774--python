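"""Residual U-net for annulus segmentation.

A contracting path of residual convolution blocks with 2x2 max-pooling, a
bottleneck block, and an expanding path of stride-2 transposed convolutions
whose outputs are concatenated with the matching contracting-path features
before each decoder block. A final 1x1 convolution maps to per-class
logits, so a 1 x H x W image yields a C x H x W logit map at the input
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import layers as _layers
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    Layer,
    MaxPool2x2,
    ResidualBlock,
    _Sequential,
)


def layers_dtype():
    return _layers.DTYPE


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**(depth - 1)`` so that pooled
    feature maps stay even-sized all the way down.
    """

    n_classes: int = 3
    depth: int = 5
    base_channels: int = 32
    input_size: int = 224

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2**(depth-1) = {2 ** (self.depth - 1)}"
            )


class ResidualUNet(Layer):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        b, d = config.base_channels, config.depth

        self.enc_blocks: list[ResidualBlock] = []
        self.pools: list[MaxPool2x2] = []
        c_prev = 1
        for lvl in range(d - 1):
            c = b * 2 ** lvl
            self.enc_blocks.append(ResidualBlock(c_prev, c, rng=rng))
            self.pools.append(MaxPool2x2())
            c_prev = c
        self.bottleneck = ResidualBlock(c_prev, b * 2 ** (d - 1), rng=rng)
        c_prev = b * 2 ** (d - 1)

        self.ups: list[ConvTranspose2x2] = []
        self.dec_blocks: list[ResidualBlock] = []
        for lvl in reversed(range(d - 1)):
            c = b * 2 ** lvl
            self.ups.append(ConvTranspose2x2(c_prev, c, rng=rng))
            self.dec_blocks.append(ResidualBlock(2 * c, c, rng=rng))
            c_prev = c
        self.head = Conv2d(c_prev, config.n_classes, 1, rng=rng)

    # -- parameter plumbing -------------------------------------------------

    def _named_children(self):
        for i, blk in enumerate(self.enc_blocks):
            yield f"enc{i}", blk
        yield "bottleneck", self.bottleneck
        for i, (up, blk) in enumerate(zip(self.ups, self.dec_blocks)):
            yield f"up{i}", up
            yield f"dec{i}", blk
        yield "head", self.head

    def named_params(self):
        out = []
        for cname, child in self._named_children():
            out += [(f"{cname}.{n}", p, g) for n, p, g in child.named_params()]
        return out

    def batchnorms(self):
        """All BatchNorm2d instances, in a stable order, with path names."""
        found = []

        def visit(prefix, layer):
            if isinstance(layer, BatchNorm2d):
                found.append((prefix, layer))
            elif isinstance(layer, ResidualBlock):
                for n, c in layer._children().items():
                    visit(f"{prefix}.{n}", c)
            elif isinstance(layer, _Sequential):
                for i, c in enumerate(layer.layers):
                    visit(f"{prefix}.{i}", c)

        for cname, child in self._named_children():
            visit(cname, child)
        return found

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.named_params())

    # -- forward / backward -------------------------------------------------

    def forward(self, x, train=False):
        """Map images to per-class logits.

        Accepts ``(N, H, W)`` or ``(N, 1, H, W)`` input and returns
        ``(N, C, H, W)`` logits; computation is channels-last internally.
        """
        x = np.asarray(x, dtype=layers_dtype())
        if x.ndim == 4:  # NCHW with a single channel
            x = x[:, 0]
        x = x[..., None]  # -> NHWC
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = blk.forward(np.concatenate([skip, x], axis=-1), train)
        out = self.head.forward(x, train)
        return out.transpose(0, 3, 1, 2)

    def backward(self, dy):
        """Backpropagate d(loss)/d(logits) given in NCHW layout."""
        d = self.head.backward(np.ascontiguousarray(dy.transpose(0, 2, 3, 1)))
        dskips = []
        for up, blk, c_skip in zip(reversed(self.ups), reversed(self.dec_blocks),
                                   reversed(self._skip_channels)):
            dcat = blk.backward(d)
            dskips.append(np.ascontiguousarray(dcat[..., :c_skip]))
            d = np.ascontiguousarray(dcat[..., c_skip:])
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips[0] belongs to the shallowest encoder block (last decoder stage)
        for blk, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)
        return d


def build_network(config: NetworkConfig, seed: int = 0) -> ResidualUNet:
    """Construct a seeded, He-initialized residual U-net."""
    return ResidualUNet(config, rng=np.random.default_rng(seed))
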
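"""Segmentation heads that turn an encoder feature pyramid into per-pixel
foreground logits.

All decoders accept the 5-level pyramid ``[f1@/2 ... f5@/32]`` and emit
(N, H, W, 1) logits at input resolution.  Upsampling is nearest-neighbour:
on feature maps (not masks) the interpolation family is immaterial at this
scale and nearest keeps the backward pass trivial.

Faithfulness note: block structure follows each family's published design
(U-shaped concat-skip decoding; nested dense skips; atrous spatial pyramid
pooling; additive link decoding; attention-gated multi-scale fusion), with
channel widths kept configurable so the suite runs on CPU.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Sequence

import numpy as np

from ..nn import ConvBnAct, Identity, Module, ModuleList, SEBlock
from ..nn import tensor as T
from ..nn.layers import Conv2d
from ..nn.tensor import Tensor

__all__ = ["DECODERS", "build_decoder", "register_decoder"]

DECODERS: Dict[str, Callable[..., "Decoder"]] = {}

#: Decoder widths from deep to shallow; compact by design so CPU runs stay fast.
DEFAULT_DECODER_CHANNELS = (64, 48, 32, 24, 16)


def register_decoder(name: str):
    def deco(factory):
        DECODERS[name] = factory
        return factory

    return deco


def build_decoder(name: str, encoder_channels: Sequence[int]) -> "Decoder":
    try:
        factory = DECODERS[name]
    except KeyError:
        raise KeyError(
            f"unknown decoder {name!r}; registered decoders: {sorted(DECODERS)}"
        ) from None
    return factory(list(encoder_channels))


class Decoder(Module):
    pass


class _DecodeBlock(Module):
    """upsample x2 -> concat skip -> two conv-bn-relu."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int) -> None:
        super().__init__()
        self.conv1 = ConvBnAct(in_ch + skip_ch, out_ch, 3)
        self.conv2 = ConvBnAct(out_ch, out_ch, 3)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = T.upsample_nearest(x, 2)
        if skip is not None:
            x = T.concat([x, skip])
        return self.conv2(self.conv1(x))


@register_decoder("unet")
class UNetDecoder(Decoder):
    """Symmetric U-shape: five upsampling stages with concatenated skips."""

    def __init__(
        self,
        encoder_channels: Sequence[int],
        decoder_channels: Sequence[int] = DEFAULT_DECODER_CHANNELS,
    ) -> None:
        super().__init__()
        enc = list(encoder_channels)  # [f1..f5]
        skips = [enc[3], enc[2], enc[1], enc[0], 0]
        blocks = []
        in_ch = enc[4]
        for skip_ch, out_ch in zip(skips, decoder_channels):
            blocks.append(_DecodeBlock(in_ch, skip_ch, out_ch))
            in_ch = out_ch
        self.blocks = ModuleList(blocks)
        self.head = Conv2d(in_ch, 1, kernel=3)

    def forward(self, feats: List[Tensor]) -> Tensor:
        f1, f2, f3, f4, f5 = feats
        x = f5
        for block, skip in zip(self.blocks, [f4, f3, f2, f1, None]):
            x = block(x, skip)
        return self.head(x)


@register_decoder("unetpp")
class UNetPPDecoder(Decoder):
    """Nested dense skips: every node re-aggregates all shallower nodes at
    its level plus the upsampled deeper node."""

    def __init__(
        self,
        encoder_channels: Sequence[int],
        decoder_channels: Sequence[int] = DEFAULT_DECODER_CHANNELS,
    ) -> None:
        super().__init__()
        enc = list(encoder_channels)
        # width of node X[i][j]: row i (level, 0 = /2), column j >= 1
        self._depth = 4
        width = {(i, 0): enc[i] for i in range(5)}
        blocks = {}
        level_width = list(decoder_channels)[::-1]  # shallow levels stay narrow
        for j in range(1, 5):
            for i in range(0, 5 - j):
                out_ch = level_width[i]
                in_ch = sum(width[(i, k)] for k in range(j)) + width[(i + 1, j - 1)]
                blocks[f"x_{i}_{j}"] = _NestedBlock(in_ch, out_ch)
                width[(i, j)] = out_ch
        self.grid = ModuleList([blocks[k] for k in sorted(blocks)])
        self._keys = sorted(blocks)
        self.final_up = _DecodeBlock(width[(0, 4)], 0, decoder_channels[-1])
        self.head = Conv2d(decoder_channels[-1], 1, kernel=3)

    def forward(self, feats: List[Tensor]) -> Tensor:
        nodes = {(i, 0): f for i, f in enumerate(feats)}
        modules = dict(zip(self._keys, self.grid))
        for j in range(1, 5):
            for i in range(0, 5 - j):
                parts = [nodes[(i, k)] for k in range(j)]
                parts.append(T.upsample_nearest(nodes[(i + 1, j - 1)], 2))
                nodes[(i, j)] = modules[f"x_{i}_{j}"](T.concat(parts))
        x = self.final_up(nodes[(0, 4)], None)  # /2 -> /1
        return self.head(x)


class _NestedBlock(Module):
    def __init__(self, in_ch: int, out_ch: int) -> None:
        super().__init__()
        self.conv = ConvBnAct(in_ch, out_ch, 3)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


@register_decoder("deeplabv3")
class DeepLabV3Decoder(Decoder):
    """Atrous spatial pyramid pooling over the deepest features, then a
    direct upsample back to input resolution."""

    RATES = (2, 4, 6)  # scaled down for the small feature maps used here

    def __init__(
        self,
        encoder_channels: Sequence[int],
        out_ch: int = 64,
    ) -> None:
        super().__init__()
        deep = list(encoder_channels)[4]
        self.branch1 = ConvBnAct(deep, out_ch, 1)
        self.branches = ModuleList(
            [ConvBnAct(deep, out_ch, 3, dilation=r) for r in self.RATES]
        )
        self.pool_proj = ConvBnAct(deep, out_ch, 1)
        self.project = ConvBnAct(out_ch * (2 + len(self.RATES)), out_ch, 1)
        self.refine = ConvBnAct(out_ch, out_ch, 3)
        self.head = Conv2d(out_ch, 1, kernel=1, padding=0)

    def forward(self, feats: List[Tensor]) -> Tensor:
        f5 = feats[4]
        h, w = f5.shape[1], f5.shape[2]
        pooled = self.pool_proj(T.global_avg_pool(f5))
        # broadcast the (N,1,1,C) image-pooling branch back to the grid
        pooled = T.mul(pooled, np.ones((1, h, w, 1), dtype=np.float32))
        parts = [self.branch1(f5)] + [b(f5) for b in self.branches] + [pooled]
        x = self.refine(self.project(T.concat(parts)))
        return T.upsample_nearest(self.head(x), 32)


@register_decoder("linknet")
class LinkNetDecoder(Decoder):
    """Additive links: each decoder block reduces, upsamples and expands,
    then adds the encoder feature of the matching level."""

    def __init__(self, encoder_channels: Sequence[int]) -> None:
        super().__init__()
        enc = list(encoder_channels)
        blocks = []
        for i in range(4, 0, -1):
            blocks.append(_LinkBlock(enc[i], enc[i - 1]))
        self.blocks = ModuleList(blocks)
        self.final = _LinkBlock(enc[0], 16)
        self.head = Conv2d(16, 1, kernel=3)

    def forward(self, feats: List[Tensor]) -> Tensor:
        x = feats[4]
        for block, skip in zip(self.blocks, [feats[3], feats[2], feats[1], feats[0]]):
            x = T.add(block(x), skip)
        x = self.final(x)  # /2 -> /1
        return self.head(x)


class _LinkBlock(Module):
    def __init__(self, in_ch: int, out_ch: int) -> None:
        super().__init__()
        mid = max(in_ch // 4, 8)
        self.reduce = ConvBnAct(in_ch, mid, 1)
        self.conv = ConvBnAct(mid, mid, 3)
        self.expand = ConvBnAct(mid, out_ch, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.expand(self.conv(T.upsample_nearest(self.reduce(x), 2)))


@register_decoder("manet")
class MANetDecoder(Decoder):
    """Multi-scale attention aggregation: U-shaped decoding where each fusion
    re-weights channels of the concatenated features from pooled descriptors
    before convolving (squeeze-excitation-style attention per stage)."""

    def __init__(
        self,
        encoder_channels: Sequence[int],
        decoder_channels: Sequence[int] = DEFAULT_DECODER_CHANNELS,
    ) -> None:
        super().__init__()
        enc = list(encoder_channels)
        skips = [enc[3], enc[2], enc[1], enc[0], 0]
        blocks = []
        in_ch = enc[4]
        for skip_ch, out_ch in zip(skips, decoder_channels):
            blocks.append(_AttnFuseBlock(in_ch, skip_ch, out_ch))
            in_ch = out_ch
        self.blocks = ModuleList(blocks)
        self.head = Conv2d(in_ch, 1, kernel=3)

    def forward(self, feats: List[Tensor]) -> Tensor:
        f1, f2, f3, f4, f5 = feats
        x = f5
        for block, skip in zip(self.blocks, [f4, f3, f2, f1, None]):
            x = block(x, skip)
        return self.head(x)


class _AttnFuseBlock(Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int) -> None:
        super().__init__()
        total = in_ch + skip_ch
        self.attn = SEBlock(total, reduction=8) if skip_ch else Identity()
        self.conv1 = ConvBnAct(total, out_ch, 3)
        self.conv2 = ConvBnAct(out_ch, out_ch, 3)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = T.upsample_nearest(x, 2)
        if skip is not None:
            x = self.attn(T.concat([x, skip]))
        return self.conv2(self.conv1(x))
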
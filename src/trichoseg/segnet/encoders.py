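"""Feature-extractor backbones.

Contract: ``forward(x)`` on an (N, H, W, 3) batch returns a five-level
feature pyramid ``[f1, ..., f5]`` at strides 2, 4, 8, 16 and 32, and
``out_channels`` lists the channel width at each level.  H and W must be
divisible by 32.

Registered families mirror widely used classification backbones at their
published depths and widths: VGG-19 with batch norm, ResNet-18/50,
SE-ResNet-50, RegNetX-6.4GF and EfficientNet-B5, plus a deliberately small
``tiny`` backbone so the full pipeline trains in seconds on a CPU.  All
weights are randomly initialized; loading externally pretrained weights is
not supported in this offline implementation.
"""

from __future__ import annotations

from typing import Callable, Dict, List

from ..nn import ConvBnAct, Identity, Module, ModuleList, SEBlock, Sequential
from ..nn import tensor as T
from ..nn.tensor import Tensor

__all__ = ["ENCODERS", "build_encoder", "register_encoder"]

ENCODERS: Dict[str, Callable[[], "Encoder"]] = {}


def register_encoder(name: str):
    def deco(factory):
        ENCODERS[name] = factory
        return factory

    return deco


def build_encoder(name: str) -> "Encoder":
    try:
        factory = ENCODERS[name]
    except KeyError:
        raise KeyError(
            f"unknown encoder {name!r}; registered encoders: {sorted(ENCODERS)}"
        ) from None
    return factory()


class Encoder(Module):
    out_channels: List[int]


# ---------------------------------------------------------------------------
# tiny: 4 conv blocks, narrow channels — the CPU-test backbone


@register_encoder("tiny")
class TinyEncoder(Encoder):
    def __init__(self) -> None:
        super().__init__()
        widths = [8, 16, 24, 32, 32]
        self.out_channels = widths
        blocks = []
        in_ch = 3
        for wdt in widths:
            blocks.append(ConvBnAct(in_ch, wdt, 3))
            in_ch = wdt
        self.blocks = ModuleList(blocks)

    def forward(self, x: Tensor) -> List[Tensor]:
        feats = []
        for block in self.blocks:
            x = T.max_pool2d(block(x), 2)
            feats.append(x)
        return feats


# ---------------------------------------------------------------------------
# VGG-19 with batch normalization (configuration E)


@register_encoder("vgg19bn")
class VGG19BNEncoder(Encoder):
    STAGES = [(64, 2), (128, 2), (256, 4), (512, 4), (512, 4)]

    def __init__(self) -> None:
        super().__init__()
        self.out_channels = [w for w, _ in self.STAGES]
        stages = []
        in_ch = 3
        for width, depth in self.STAGES:
            convs = []
            for _ in range(depth):
                convs.append(ConvBnAct(in_ch, width, 3))
                in_ch = width
            stages.append(Sequential(*convs))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> List[Tensor]:
        feats = []
        for stage in self.stages:
            x = T.max_pool2d(stage(x), 2)
            feats.append(x)
        return feats


# ---------------------------------------------------------------------------
# ResNet family


class BasicBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1) -> None:
        super().__init__()
        self.conv1 = ConvBnAct(in_ch, out_ch, 3, stride=stride)
        self.conv2 = ConvBnAct(out_ch, out_ch, 3, act="none")
        self.down = (
            ConvBnAct(in_ch, out_ch, 1, stride=stride, act="none")
            if stride != 1 or in_ch != out_ch
            else Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(T.add(self.conv2(self.conv1(x)), self.down(x)))


class Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int = 1, se: bool = False) -> None:
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = ConvBnAct(in_ch, mid_ch, 1)
        self.conv2 = ConvBnAct(mid_ch, mid_ch, 3, stride=stride)
        self.conv3 = ConvBnAct(mid_ch, out_ch, 1, act="none")
        self.se = SEBlock(out_ch) if se else Identity()
        self.down = (
            ConvBnAct(in_ch, out_ch, 1, stride=stride, act="none")
            if stride != 1 or in_ch != out_ch
            else Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        y = self.se(self.conv3(self.conv2(self.conv1(x))))
        return T.relu(T.add(y, self.down(x)))


class ResNetEncoder(Encoder):
    def __init__(self, depths: List[int], bottleneck: bool, se: bool = False) -> None:
        super().__init__()
        self.stem = ConvBnAct(3, 64, 7, stride=2)
        widths = [64, 128, 256, 512]
        exp = Bottleneck.expansion if bottleneck else 1
        self.out_channels = [64] + [w * exp for w in widths]
        stages = []
        in_ch = 64
        for i, (width, depth) in enumerate(zip(widths, depths)):
            blocks = []
            for j in range(depth):
                stride = 2 if (j == 0 and i > 0) else 1
                if bottleneck:
                    blocks.append(Bottleneck(in_ch, width, stride=stride, se=se))
                    in_ch = width * exp
                else:
                    blocks.append(BasicBlock(in_ch, width, stride=stride))
                    in_ch = width
            stages.append(Sequential(*blocks))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> List[Tensor]:
        f1 = self.stem(x)  # /2
        x = T.max_pool2d(f1, 2)  # /4
        feats = [f1]
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


@register_encoder("resnet18")
def _resnet18() -> ResNetEncoder:
    return ResNetEncoder([2, 2, 2, 2], bottleneck=False)


@register_encoder("resnet50")
def _resnet50() -> ResNetEncoder:
    return ResNetEncoder([3, 4, 6, 3], bottleneck=True)


@register_encoder("se_resnet50")
def _se_resnet50() -> ResNetEncoder:
    return ResNetEncoder([3, 4, 6, 3], bottleneck=True, se=True)


# ---------------------------------------------------------------------------
# RegNetX-6.4GF: grouped-conv X blocks, widths/depths from the design-space
# exploration family


class XBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, group_width: int) -> None:
        super().__init__()
        groups = max(out_ch // group_width, 1)
        self.conv1 = ConvBnAct(in_ch, out_ch, 1)
        self.conv2 = ConvBnAct(out_ch, out_ch, 3, stride=stride, groups=groups)
        self.conv3 = ConvBnAct(out_ch, out_ch, 1, act="none")
        self.down = (
            ConvBnAct(in_ch, out_ch, 1, stride=stride, act="none")
            if stride != 1 or in_ch != out_ch
            else Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(T.add(self.conv3(self.conv2(self.conv1(x))), self.down(x)))


@register_encoder("regnetx064")
class RegNetX064Encoder(Encoder):
    WIDTHS = [168, 392, 784, 1624]
    DEPTHS = [2, 4, 10, 1]
    GROUP_WIDTH = 56

    def __init__(self) -> None:
        super().__init__()
        self.stem = ConvBnAct(3, 32, 3, stride=2)
        self.out_channels = [32] + self.WIDTHS
        stages = []
        in_ch = 32
        for width, depth in zip(self.WIDTHS, self.DEPTHS):
            blocks = []
            for j in range(depth):
                blocks.append(XBlock(in_ch, width, 2 if j == 0 else 1, self.GROUP_WIDTH))
                in_ch = width
            stages.append(Sequential(*blocks))
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> List[Tensor]:
        x = self.stem(x)
        feats = [x]
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


# ---------------------------------------------------------------------------
# EfficientNet-B5: MBConv blocks with squeeze-excitation and SiLU


class MBConv(Module):
    def __init__(
        self, in_ch: int, out_ch: int, kernel: int, stride: int, expand: int
    ) -> None:
        super().__init__()
        mid = in_ch * expand
        self.expand = ConvBnAct(in_ch, mid, 1, act="silu") if expand != 1 else Identity()
        self.dw = ConvBnAct(mid, mid, kernel, stride=stride, groups=mid, act="silu")
        self.se = SEBlock(mid, reduction=4 * expand)
        self.project = ConvBnAct(mid, out_ch, 1, act="none")
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.se(self.dw(self.expand(x))))
        return T.add(y, x) if self.residual else y


@register_encoder("effnet_b5")
class EfficientNetB5Encoder(Encoder):
    # (width, depth, expand, kernel, stride) per stage, B5 scaling
    STAGES = [
        (24, 3, 1, 3, 1),
        (40, 5, 6, 3, 2),
        (64, 5, 6, 5, 2),
        (128, 7, 6, 3, 2),
        (176, 7, 6, 5, 1),
        (304, 9, 6, 5, 2),
        (512, 3, 6, 3, 1),
    ]
    #: stage index after which each pyramid level is emitted
    _FEATURE_STAGES = {0: 0, 1: 1, 2: 2, 4: 3, 6: 4}

    def __init__(self) -> None:
        super().__init__()
        self.stem = ConvBnAct(3, 48, 3, stride=2, act="silu")
        stages = []
        in_ch = 48
        for width, depth, expand, kernel, stride in self.STAGES:
            blocks = []
            for j in range(depth):
                blocks.append(
                    MBConv(in_ch, width, kernel, stride if j == 0 else 1, expand)
                )
                in_ch = width
            stages.append(Sequential(*blocks))
        self.stages = ModuleList(stages)
        self.out_channels = [24, 40, 64, 176, 512]

    def forward(self, x: Tensor) -> List[Tensor]:
        x = self.stem(x)
        feats = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in self._FEATURE_STAGES:
                feats.append(x)
        return feats
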
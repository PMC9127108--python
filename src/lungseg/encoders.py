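"""Encoder backbones for the segmentation U-Net.

Two families are provided:

* ``tiny_test`` — a 5-stage strided-conv pyramid with widths (8, 16, 32, 64,
  128), small enough (< 500k parameters with its matching decoder) for fast
  CPU training in tests and demos.
* ``efficientnet_b4_random`` — the EfficientNet-B4 topology (MBConv blocks
  with expansion, depthwise convolution and squeeze-excitation, at the B4
  width/depth scaling) with randomly initialized weights. ImageNet-pretrained
  weights cannot be fetched in an offline install, so requesting
  ``efficientnet_b4_pretrained`` raises with a pointer to the alternatives.

Every encoder returns five feature maps at strides 2, 4, 8, 16 and 32; the
decoder consumes the stride-32 map and uses the other four as skips.
"""

from __future__ import annotations

import numpy as np

from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, LeakyReLU, Module, Sequential, Swish
from .nn.autograd import Tensor

ENCODER_NAMES = ("efficientnet_b4_pretrained", "efficientnet_b4_random", "tiny_test")


class PretrainedWeightsUnavailableError(RuntimeError):
    """Raised when ImageNet weights are requested but cannot be loaded."""


TINY_WIDTHS = (8, 16, 32, 64, 128)


class TinyEncoder(Module):
    """Five stride-2 conv/BN/LeakyReLU stages; widths (8, 16, 32, 64, 128)."""

    out_channels = TINY_WIDTHS

    def __init__(self, in_channels: int = 3, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        stages = []
        cin = in_channels
        for width in TINY_WIDTHS:
            stages.append(
                Sequential(
                    Conv2d(cin, width, 3, stride=2, bias=False, rng=rng),
                    BatchNorm2d(width),
                    LeakyReLU(0.01),
                )
            )
            cin = width
        self.stages = stages

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


class SqueezeExcite(Module):
    """Channel attention: global pool -> reduce -> swish -> expand -> sigmoid."""

    def __init__(self, channels: int, reduced: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.reduce = Conv2d(channels, reduced, 1, rng=rng)
        self.expand = Conv2d(reduced, channels, 1, rng=rng)
        self.act = Swish()

    def forward(self, x: Tensor) -> Tensor:
        s = ag.mean_axes(x, axes=(2, 3), keepdims=True)
        s = ag.sigmoid(self.expand(self.act(self.reduce(s))))
        return ag.mul(x, s)


class MBConv(Module):
    """Mobile inverted bottleneck block with squeeze-excitation."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        stride: int,
        expand_ratio: int,
        se_ratio: float,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        cmid = cin * expand_ratio
        self.use_residual = stride == 1 and cin == cout
        self.expand = (
            Sequential(Conv2d(cin, cmid, 1, bias=False, rng=rng), BatchNorm2d(cmid), Swish())
            if expand_ratio != 1
            else None
        )
        self.depthwise = Sequential(
            Conv2d(cmid, cmid, kernel, stride=stride, bias=False, depthwise=True, rng=rng),
            BatchNorm2d(cmid),
            Swish(),
        )
        self.se = SqueezeExcite(cmid, max(1, int(cin * se_ratio)), rng)
        self.project = Sequential(
            Conv2d(cmid, cout, 1, bias=False, rng=rng), BatchNorm2d(cout)
        )

    def forward(self, x: Tensor) -> Tensor:
        h = x if self.expand is None else self.expand(x)
        h = self.project(self.se(self.depthwise(h)))
        return ag.add(h, x) if self.use_residual else h


# (expand_ratio, kernel, stride, out_channels, repeats) at B4 scaling
_B4_STAGES = (
    (1, 3, 1, 24, 2),
    (6, 3, 2, 32, 4),
    (6, 5, 2, 56, 4),
    (6, 3, 2, 112, 6),
    (6, 5, 1, 160, 6),
    (6, 5, 2, 272, 8),
    (6, 3, 1, 448, 2),
)
_B4_STEM = 48
# features handed to the decoder: after stages 0, 1, 2, 4, 6 (strides 2..32)
_B4_TAPS = (0, 1, 2, 4, 6)


class EfficientNetB4Encoder(Module):
    """EfficientNet-B4 feature pyramid, randomly initialized."""

    out_channels = tuple(_B4_STAGES[i][3] for i in _B4_TAPS)  # (24, 32, 56, 160, 448)

    def __init__(self, in_channels: int = 3, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stem = Sequential(
            Conv2d(in_channels, _B4_STEM, 3, stride=2, bias=False, rng=rng),
            BatchNorm2d(_B4_STEM),
            Swish(),
        )
        self.stages: list[Sequential] = []
        cin = _B4_STEM
        for expand, kernel, stride, cout, repeats in _B4_STAGES:
            blocks = []
            for r in range(repeats):
                blocks.append(
                    MBConv(cin, cout, kernel, stride if r == 0 else 1, expand, 0.25, rng)
                )
                cin = cout
            self.stages.append(Sequential(*blocks))

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem(x)
        feats = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in _B4_TAPS:
                feats.append(x)
        return feats


def build_encoder(name: str, rng: np.random.Generator) -> Module:
    if name == "tiny_test":
        return TinyEncoder(rng=rng)
    if name == "efficientnet_b4_random":
        return EfficientNetB4Encoder(rng=rng)
    if name == "efficientnet_b4_pretrained":
        raise PretrainedWeightsUnavailableError(
            "ImageNet-pretrained EfficientNet-B4 weights are not available in this "
            "installation; use encoder='efficientnet_b4_random' for the same topology "
            "with random init, or 'tiny_test' for a small CPU-friendly backbone."
        )
    raise ValueError(f"unknown encoder {name!r}; choose one of {ENCODER_NAMES}")
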
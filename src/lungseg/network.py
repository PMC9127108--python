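"""The improved U-Net for lung-field segmentation.

Architecture: a 5-stage encoder produces features at strides 2–32; five
decoder stages mirror them. Each decoder stage upsamples 2× (nearest
neighbour), concatenates the same-resolution encoder skip, then applies the
residual decoder sub-block: dropout → padded 3×3 convolution → a configurable
number of residual blocks (default two) → LeakyReLU. A 1×1 convolution with a
sigmoid head emits a single-channel probability map at the input resolution.

The residual block computes ``x + C(B(x))`` — a two-convolution branch with
batch normalization added back onto an unmodified identity shortcut — so
gradients reach early layers without attenuation through the branch.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .encoders import ENCODER_NAMES, TINY_WIDTHS, build_encoder
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, Dropout, LeakyReLU, Module, Sequential

__all__ = [
    "ConfigError",
    "ModelConfig",
    "ResidualBlock",
    "DecoderBlock",
    "UNet",
    "assemble_model",
    "predict_mask",
    "relu",
    "leaky_relu",
    "save_weights",
    "load_weights",
]


class ConfigError(ValueError):
    """Invalid model configuration; the message names the offending field."""


#: decoder widths per encoder family when the user leaves decoder_channels unset
_DEFAULT_DECODER_CHANNELS = {
    "tiny_test": (32, 24, 16, 12, 8),
    "efficientnet_b4_random": (256, 128, 64, 32, 16),
    "efficientnet_b4_pretrained": (256, 128, 64, 32, 16),
}


@dataclass
class ModelConfig:
    """Architecture knobs for :func:`assemble_model`."""

    input_size: int = 256
    input_channels: int = 3
    encoder: str = "efficientnet_b4_random"
    decoder_channels: tuple[int, ...] | None = None
    residual_blocks_per_decoder: int = 2
    activation: str = "leaky_relu"
    leaky_slope: float = 0.01
    dropout_rate: float = 0.2

    def validate(self) -> "ModelConfig":
        if self.input_size < 32 or self.input_size % 32 != 0:
            raise ConfigError(
                f"input_size must be >= 32 and divisible by 32 "
                f"(five 2x downsamplings), got {self.input_size}"
            )
        if self.input_channels != 3:
            raise ConfigError(f"input_channels must be 3, got {self.input_channels}")
        if self.encoder not in ENCODER_NAMES:
            raise ConfigError(f"encoder must be one of {ENCODER_NAMES}, got {self.encoder!r}")
        if self.decoder_channels is not None:
            if len(self.decoder_channels) != 5 or any(c < 1 for c in self.decoder_channels):
                raise ConfigError(
                    f"decoder_channels must be 5 positive integers, got {self.decoder_channels}"
                )
        if self.residual_blocks_per_decoder < 0:
            raise ConfigError(
                f"residual_blocks_per_decoder must be >= 0, "
                f"got {self.residual_blocks_per_decoder}"
            )
        if self.activation not in ("relu", "leaky_relu"):
            raise ConfigError(f"activation must be 'relu' or 'leaky_relu', got {self.activation!r}")
        if self.leaky_slope <= 0:
            raise ConfigError(f"leaky_slope must be positive, got {self.leaky_slope}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        return self

    def resolved_decoder_channels(self) -> tuple[int, ...]:
        if self.decoder_channels is not None:
            return tuple(self.decoder_channels)
        return _DEFAULT_DECODER_CHANNELS[self.encoder]

    @property
    def act_slope(self) -> float:
        return self.leaky_slope if self.activation == "leaky_relu" else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["decoder_channels"] is not None:
            d["decoder_channels"] = list(d["decoder_channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("decoder_channels") is not None:
            d["decoder_channels"] = tuple(d["decoder_channels"])
        return cls(**d).validate()


# ---------------------------------------------------------------------------
# elementwise activations on plain numbers/arrays (reference definitions)
# ---------------------------------------------------------------------------

def leaky_relu(x, slope: float = 0.01):
    """x for x >= 0, slope*x otherwise."""
    return np.where(np.asarray(x) >= 0, x, slope * np.asarray(x))[()]


def relu(x):
    """max(x, 0)."""
    return np.maximum(x, 0)[()]


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ResidualBlock(Module):
    """out = x + branch(x); branch = conv3x3-BN-activation-conv3x3-BN.

    The shortcut adds the input unchanged, so when every branch parameter is
    zero the block is exactly the identity, and the gradient w.r.t. the input
    is (identity + branch Jacobian) times the upstream gradient.
    """

    def __init__(self, channels: int, slope: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.branch = Sequential(
            Conv2d(channels, channels, 3, bias=False, rng=rng),
            BatchNorm2d(channels),
            LeakyReLU(slope),
            Conv2d(channels, channels, 3, bias=False, rng=rng),
            BatchNorm2d(channels),
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.branch.layers[0].weight.data.shape[1]:
            raise ValueError(
                f"residual block expects {self.branch.layers[0].weight.data.shape[1]} "
                f"channels, got {x.data.shape[1]}"
            )
        return ag.add(x, self.branch(x))

    def zero_branch(self) -> None:
        """Zero every branch parameter (turns the block into the identity)."""
        for p in self.branch.parameters():
            p.data[...] = 0.0


class DecoderBlock(Module):
    """One decoder stage: up 2x, concat skip, dropout -> conv -> residual blocks -> act."""

    def __init__(
        self,
        in_channels: int,
        skip_channels: int,
        out_channels: int,
        n_residual: int,
        slope: float,
        dropout_rate: float,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.skip_channels = skip_channels
        self.dropout = Dropout(dropout_rate)
        self.conv = Conv2d(in_channels + skip_channels, out_channels, 3, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.residual_blocks = [
            ResidualBlock(out_channels, slope, rng) for _ in range(n_residual)
        ]
        self.act = LeakyReLU(slope)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = ag.upsample_nearest2x(x)
        if skip is not None:
            if x.data.shape[2:] != skip.data.shape[2:]:
                raise ValueError(
                    f"decoder skip mismatch: upsampled features are "
                    f"{x.data.shape[2:]}, skip is {skip.data.shape[2:]}"
                )
            x = ag.concat([x, skip], axis=1)
        x = self.bn(self.conv(self.dropout(x)))
        for block in self.residual_blocks:
            x = block(x)
        return self.act(x)


class UNet(Module):
    """Encoder–decoder segmentation network with sigmoid mask head."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = build_encoder(config.encoder, rng)
        enc_channels = self.encoder.out_channels  # strides 2, 4, 8, 16, 32
        dec_channels = config.resolved_decoder_channels()
        # decoder stage i consumes the previous stage's output and the skip
        # four stages down; the fifth stage (stride 2 -> 1) has no skip.
        skips = list(enc_channels[-2::-1]) + [0]  # (s16, s8, s4, s2, none)
        ins = [enc_channels[-1]] + list(dec_channels[:-1])
        self.decoder_blocks = [
            DecoderBlock(
                cin,
                cskip,
                cout,
                config.residual_blocks_per_decoder,
                config.act_slope,
                config.dropout_rate,
                rng,
            )
            for cin, cskip, cout in zip(ins, skips, dec_channels)
        ]
        self.head = Conv2d(dec_channels[-1], 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encoder(x)
        h = feats[-1]
        skips = feats[-2::-1] + [None]
        for block, skip in zip(self.decoder_blocks, skips):
            h = block(h, skip)
        return ag.sigmoid(self.head(h))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def reseed_dropout(self, seed: int) -> None:
        for i, mod in enumerate(m for m in self.modules() if isinstance(m, Dropout)):
            mod.reseed(seed + i)


def assemble_model(config: ModelConfig, seed: int = 0) -> UNet:
    """Build the segmentation network described by ``config``.

    Weight initialization is He-normal, deterministic in ``seed``.
    """
    return UNet(config, seed=seed)


def predict_mask(network: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Run the network on one H×W×3 image and binarize at ``threshold``.

    Returns a boolean H×W mask (probability >= threshold). The sigmoid output
    is strictly inside (0, 1), so threshold 0 gives all-foreground and
    threshold 1 all-background.
    """
    size = network.config.input_size
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (size, size, 3):
        raise ValueError(
            f"expected input of shape ({size}, {size}, 3) for this model, "
            f"got {image.shape}"
        )
    was_training = network.training
    network.eval()
    probs = network(Tensor(image.transpose(2, 0, 1)[None])).data[0, 0]
    if was_training:
        network.train()
    return probs >= threshold


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_weights(network: UNet, path: str | Path) -> None:
    """Save parameters + batch-norm buffers (npz) and config (yaml sidecar)."""
    path = Path(path)
    arrays = {f"param/{k}": v.data for k, v in network.named_parameters().items()}
    for i, mod in enumerate(m for m in network.modules() if isinstance(m, BatchNorm2d)):
        arrays[f"bn/{i}/mean"] = mod.running_mean
        arrays[f"bn/{i}/var"] = mod.running_var
    np.savez(path, **arrays)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump({"model": network.config.to_dict()}, fh)


def load_weights(network: UNet, path: str | Path) -> UNet:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        named = network.named_parameters()
        for key, tensor in named.items():
            tensor.data[...] = data[f"param/{key}"]
        bns = [m for m in network.modules() if isinstance(m, BatchNorm2d)]
        for i, mod in enumerate(bns):
            mod.running_mean[...] = data[f"bn/{i}/mean"]
            mod.running_var[...] = data[f"bn/{i}/var"]
    return network
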
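"""Neural-network layers built on the autograd engine.

The Module/parameter conventions mirror the familiar torch.nn layout so the
network code reads conventionally: modules hold `Tensor` parameters with
``requires_grad=True``, `parameters()` walks the tree, `train()`/`eval()`
toggle batch-norm and dropout behaviour.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery plus train/eval mode propagation."""

    def __init__(self) -> None:
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad:
                    params.append(value)
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | str = "same",
        bias: bool = True,
        depthwise: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if padding == "same":
            padding = kernel_size // 2
        self.stride = stride
        self.padding = int(padding)
        self.depthwise = depthwise
        cin_per_filter = 1 if depthwise else in_channels
        fan_in = cin_per_filter * kernel_size * kernel_size
        self.weight = Tensor(
            _he_normal(rng, (out_channels, cin_per_filter, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            depthwise=self.depthwise,
        )


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.momentum,
            self.eps,
            self.training,
        )


class Dropout(Module):
    """Inverted dropout; the rng is reseedable for reproducible training."""

    def __init__(self, p: float, seed: int = 0) -> None:
        super().__init__()
        self.p = float(p)
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.p, self.training, self.rng)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.mul(x, ag.sigmoid(x))


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
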
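"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation network needs: broadcast
arithmetic, 2-D convolution (dense and depthwise), batch normalization,
leaky ReLU / sigmoid, nearest-neighbour upsampling, channel concatenation,
axis reductions and dropout. Gradients are hand-derived and checked against
central finite differences in the test suite.

Arrays are kept in float64 throughout: the network is small enough that the
extra precision is free, and it keeps finite-difference gradient checks sharp.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "div",
    "concat",
    "leaky_relu",
    "sigmoid",
    "conv2d",
    "batchnorm2d",
    "upsample_nearest2x",
    "sum_axes",
    "mean_axes",
    "dropout",
]


class Tensor:
    """A NumPy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep decoders overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def sum(self, axes=None, keepdims: bool = False):
        return sum_axes(self, axes, keepdims)

    def mean(self, axes=None, keepdims: bool = False):
        return mean_axes(self, axes, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    x = _as_tensor(x)
    pos = x.data >= 0
    out_data = np.where(pos, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, slope))

    return _node(out_data, (x,), backward)


_SIGMOID_CLIP = 35.0  # sigmoid(±35) is strictly inside (0, 1) in float64


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    z = np.clip(x.data, -_SIGMOID_CLIP, _SIGMOID_CLIP)
    s = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return _node(s, (x,), backward)


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def sum_axes(x: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        if axes is None:
            x._accumulate(np.broadcast_to(g, x.data.shape))
            return
        gg = g
        if not keepdims:
            ax = (axes,) if np.isscalar(axes) else tuple(axes)
            gg = np.expand_dims(g, axis=tuple(a % x.data.ndim for a in ax))
        x._accumulate(np.broadcast_to(gg, x.data.shape))

    return _node(out_data, (x,), backward)


def mean_axes(x: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    if axes is None:
        count = x.data.size
    else:
        ax = (axes,) if np.isscalar(axes) else tuple(axes)
        count = int(np.prod([x.data.shape[a] for a in ax]))
    return mul(sum_axes(x, axes, keepdims), 1.0 / count)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(ts), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: identity in eval mode or at p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return mul(x, mask)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _sliding_windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View of shape (N, C, kh, kw, Ho, Wo) over the padded input."""
    n, c, h, w = xp.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    depthwise: bool = False,
) -> Tensor:
    """2-D cross-correlation over NCHW input.

    `weight` is (C_out, C_in, kh, kw), or (C, 1, kh, kw) when depthwise.
    """
    x = _as_tensor(x)
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if depthwise:
        if cout != cin or cin_w != 1:
            raise ValueError(
                f"depthwise conv needs weight ({cin}, 1, kh, kw), got {weight.data.shape}"
            )
    elif cin_w != cin:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, weight expects {cin_w}")

    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    windows = _sliding_windows(xp, kh, kw, stride)
    ho, wo = windows.shape[4], windows.shape[5]

    if depthwise:
        out = np.einsum("ncabij,cab->ncij", windows, weight.data[:, 0], optimize=True)
    else:
        cols = np.ascontiguousarray(windows.transpose(0, 4, 5, 1, 2, 3)).reshape(
            n * ho * wo, cin * kh * kw
        )
        wmat = weight.data.reshape(cout, -1)
        out = (cols @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if depthwise:
            if weight.requires_grad:
                dw = np.einsum("ncabij,ncij->cab", windows, g, optimize=True)
                weight._accumulate(dw[:, None, :, :])
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for a in range(kh):
                    for b in range(kw):
                        dxp[
                            :, :, a : a + (ho - 1) * stride + 1 : stride,
                            b : b + (wo - 1) * stride + 1 : stride,
                        ] += g * weight.data[None, :, 0, a, b][..., None, None]
                x._accumulate(
                    dxp[:, :, padding : padding + h, padding : padding + w]
                    if padding
                    else dxp
                )
        else:
            gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
            cols_local = np.ascontiguousarray(windows.transpose(0, 4, 5, 1, 2, 3)).reshape(
                n * ho * wo, cin * kh * kw
            )
            if weight.requires_grad:
                weight._accumulate((gflat.T @ cols_local).reshape(weight.data.shape))
            if x.requires_grad:
                dcols = (gflat @ weight.data.reshape(cout, -1)).reshape(
                    n, ho, wo, cin, kh, kw
                )
                dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, kh, kw, Ho, Wo)
                dxp = np.zeros_like(xp)
                for a in range(kh):
                    for b in range(kw):
                        dxp[
                            :, :, a : a + (ho - 1) * stride + 1 : stride,
                            b : b + (wo - 1) * stride + 1 : stride,
                        ] += dcols[:, :, a, b]
                x._accumulate(
                    dxp[:, :, padding : padding + h, padding : padding + w]
                    if padding
                    else dxp
                )

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(out, parents, backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    momentum: float,
    eps: float,
    training: bool,
) -> Tensor:
    """Per-channel batch normalization over an NCHW tensor.

    In training mode normalizes with batch statistics and updates the running
    buffers in place; in eval mode uses the running buffers.
    """
    x = _as_tensor(x)
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes)
        if gamma.requires_grad:
            gamma._accumulate(dgamma)
        if beta.requires_grad:
            beta._accumulate(g.sum(axes))
        if x.requires_grad:
            scale = (gamma.data * inv_std)[None, :, None, None]
            if training:
                gmean = g.mean(axis=axes)[None, :, None, None]
                proj = (dgamma / m)[None, :, None, None]
                x._accumulate(scale * (g - gmean - xhat * proj))
            else:
                x._accumulate(scale * g)

    return _node(out, (x, gamma, beta), backward)
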
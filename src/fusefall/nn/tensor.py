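"""A compact reverse-mode autodiff engine on numpy arrays.

Everything the two classifiers need — dense/1x1 convolutions, depthwise
convolutions, batch statistics, graph propagation against a fixed adjacency
stack — is expressed through the :class:`Tensor` operations below.  Arrays are
kept in float64 so analytic gradients can be validated against central
differences to tight tolerances.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "batchnorm2d",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "graph_prop",
    "log_softmax",
    "relu",
    "clip",
    "sigmoid",
    "use_dtype",
]

#: Working precision.  float32 keeps training memory-bandwidth friendly;
#: gradient-verification tests switch to float64 via :func:`use_dtype`.
DTYPE = np.float32


@contextmanager
def use_dtype(dtype):
    global DTYPE
    old = DTYPE
    DTYPE = dtype
    try:
        yield
    finally:
        DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """N-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @classmethod
    def _result(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        out._parents = tuple(parents)
        out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be shared with (or later accumulated into) siblings
            self.grad = np.array(
                np.broadcast_to(g, self.data.shape), dtype=self.data.dtype
            )
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def build(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self.grad = (
            np.ones_like(self.data)
            if grad is None
            else np.asarray(grad, dtype=self.data.dtype)
        )
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._result(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._result(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._result(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor._result(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._result(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._result(self.data @ other.data, (self, other), bw)

    # -- elementwise -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._result(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._result(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self**0.5

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._result(self.data.transpose(axes), (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- nonlinearities --------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    return Tensor._result(x.data * mask, (x,), bw)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip with zero gradient outside [lo, hi] (used for ReLU6, BCE guards)."""
    mask = (x.data > lo) & (x.data < hi)

    def bw(g):
        x._accumulate(g * mask)

    return Tensor._result(np.clip(x.data, lo, hi), (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def bw(g):
        x._accumulate(g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))

    return Tensor._result(out_data, (x,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray,
    inv_sd: np.ndarray,
    batch_stats: bool,
) -> Tensor:
    """Fused affine normalization y = gamma * (x - mean) * inv_sd + beta.

    ``mean``/``inv_sd`` are per-channel, shaped (1, C, 1, 1).  With
    ``batch_stats`` True they were computed from ``x`` itself (training
    mode) and the backward pass includes the statistic terms; otherwise they
    are fixed running statistics.
    """
    xhat = (x.data - mean) * inv_sd
    g4 = gamma.data[None, :, None, None]
    out_data = g4 * xhat + beta.data[None, :, None, None]
    axes = (0, 2, 3)

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        if batch_stats:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            mean_g = g.sum(axis=axes, keepdims=True) / m
            mean_gx = (g * xhat).sum(axis=axes, keepdims=True) / m
            x._accumulate(g4 * inv_sd * (g - mean_g - xhat * mean_gx))
        else:
            x._accumulate(g4 * inv_sd * g)

    return Tensor._result(out_data, (x, gamma, beta), bw)


# -- structured primitives -------------------------------------------------


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    w = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::sh, ::sw]


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: tuple[int, int] = (1, 1),
    padding: tuple[int, int] = (0, 0),
) -> Tensor:
    """2-d cross-correlation, NCHW layout, weight (O, C, kh, kw).

    Implemented as im2col + matmul; the column matrix is materialized once
    and reused by the backward pass.
    """
    sh, sw = stride
    ph, pw = padding
    n, c, h, w_in = x.shape
    o, c_w, kh, kw = weight.shape
    if c != c_w:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _windows(xp, kh, kw, sh, sw)  # (N, C, Ho, Wo, kh, kw) strided view
    ho, wo = win.shape[2], win.shape[3]
    # columns: (N*Ho*Wo, C*kh*kw), contiguous once
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wmat = weight.data.reshape(o, c * kh * kw)
    out_data = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        weight._accumulate((g2.T @ cols).reshape(weight.shape))
        if bias is not None:
            bias._accumulate(g2.sum(axis=0))
        gcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        x._accumulate(gxp[:, :, ph : ph + h, pw : pw + w_in])

    return Tensor._result(out_data, parents, bw)


def depthwise_conv2d(
    x: Tensor,
    weight: Tensor,
    stride: tuple[int, int] = (1, 1),
    padding: tuple[int, int] = (0, 0),
) -> Tensor:
    """Per-channel 2-d convolution, weight (C, kh, kw)."""
    sh, sw = stride
    ph, pw = padding
    n, c, h, w_in = x.shape
    c_w, kh, kw = weight.shape
    if c != c_w:
        raise ValueError(f"depthwise channel mismatch: input {c}, weight {c_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.ascontiguousarray(_windows(xp, kh, kw, sh, sw))
    out_data = np.einsum("nchwij,cij->nchw", win, weight.data)
    ho, wo = out_data.shape[2], out_data.shape[3]

    def bw(g):
        weight._accumulate(np.einsum("nchwij,nchw->cij", win, g))
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += (
                    g * weight.data[None, :, i, j, None, None]
                )
        x._accumulate(gxp[:, :, ph : ph + h, pw : pw + w_in])

    return Tensor._result(out_data, (x, weight), bw)


def graph_prop(x: Tensor, adjacency: np.ndarray) -> Tensor:
    """Propagate node features along a stack of adjacency matrices.

    x: (N, C, T, V); adjacency: constant (K, V, V) with entry [k, v, w] the
    weight from source node v to target node w in partition k.  Output
    (N, K*C, T, V): partition-k block c holds sum_v x[:, c, :, v] * A[k, v, w].
    """
    k, v, w = adjacency.shape
    n, c, t, v_x = x.shape
    if v_x != v:
        raise ValueError(f"graph_prop node mismatch: features {v_x}, adjacency {v}")
    adjacency = adjacency.astype(x.data.dtype, copy=False)
    # (N, 1, C, T, V) @ (1, K, 1, V, W) -> (N, K, C, T, W) via batched matmul
    out5 = np.matmul(x.data[:, None], adjacency[None, :, None])

    def bw(g):
        g5 = g.reshape(n, k, c, t, w)
        gx = np.matmul(g5, np.swapaxes(adjacency, 1, 2)[None, :, None]).sum(axis=1)
        x._accumulate(gx)

    return Tensor._result(out5.reshape(n, k * c, t, w), (x,), bw)
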
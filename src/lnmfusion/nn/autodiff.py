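"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tensor engine: just the operations the encoders,
projection heads, contrastive loss and classifier need (broadcasted
arithmetic, matmul, exp/log/relu, reductions, reshape/transpose/concat,
fancy indexing, 2-D convolution and max-pooling).  Gradients are
accumulated by a topologically ordered backward sweep from a scalar loss.

All floating data is float32; gradients are float32 as well.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def T(self):
        return self.transpose()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        g = g.astype(_DTYPE, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (self._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = bwd
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes) if axes else self.data.T,
                     self.requires_grad, (self,))
        inv = np.argsort(axes) if axes else None

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv) if axes else g.T)
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    @staticmethod
    def cat(tensors: list, axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                     any(t.requires_grad for t in tensors), tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = bwd
        return out


# ------------------------------------------------------------------ conv ops

def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Ho, Wo, kh, kw) view of all stride-spaced kh x kw patches."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,Cin,H,W) with w (Cout,Cin,kh,kw)."""
    N, Cin, H, W = x.data.shape
    Cout, Cin2, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin2}")
    xp = _pad2d(x.data, padding)
    cols = _windows(xp, kh, kw, stride)          # N,Cin,Ho,Wo,kh,kw
    N_, _, Ho, Wo, _, _ = cols.shape
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho, Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out_val = (cols2 @ wmat.T).transpose(0, 3, 1, 2)      # N,Cout,Ho,Wo
    out = Tensor(out_val, x.requires_grad or w.requires_grad, (x, w))

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1)                    # N,Ho,Wo,Cout
        if w.requires_grad:
            dw = np.tensordot(gmat, cols2, axes=([0, 1, 2], [0, 1, 2]))
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols2 = gmat @ wmat                          # N,Ho,Wo,Cin*kh*kw
            dcols = dcols2.reshape(N, Ho, Wo, Cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    """Max pooling with -inf padding so pads never win the max."""
    N, C, H, W = x.data.shape
    if padding:
        xp = np.full((N, C, H + 2 * padding, W + 2 * padding),
                     -np.inf, dtype=x.data.dtype)
        xp[:, :, padding:-padding, padding:-padding] = x.data
    else:
        xp = x.data
    cols = _windows(xp, kernel, kernel, stride)           # N,C,Ho,Wo,k,k
    N_, C_, Ho, Wo, _, _ = cols.shape
    flat = cols.reshape(N, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp, dtype=_DTYPE)
        ii = arg // kernel
        jj = arg % kernel
        n_i, c_i, ho_i, wo_i = np.indices(arg.shape)
        rows = ho_i * stride + ii
        cols_ = wo_i * stride + jj
        np.add.at(dxp, (n_i, c_i, rows, cols_), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)
    out._backward = bwd
    return out
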
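"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based autograd engine providing exactly the operations the
deblurring network needs: broadcasting arithmetic, (batched) matmul, 2-D
convolution (cross-correlation convention, stride 1), depthwise convolution,
2x2 average pooling with edge-replicated ceil padding, bilinear upsampling,
layer normalization, softmax, ReLU/sigmoid, reshape/transpose/concat/slice
and reductions — plus an Adam optimizer.

Arrays keep whatever float dtype they are given (float32 for training speed,
float64 when tests compare against high-precision oracles).  All gradients are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape entries needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def _make(self, data, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        # record the tape only if some parent participates in differentiation;
        # the backward closure always returns one gradient per parent, in order
        if any(p.requires_grad or p._prev for p in prev):
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
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
            for p in node._prev:
                stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._prev, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=float))

    def __add__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            return self._make(self.data + other, (self,), lambda g: (g,))
        other = self._lift(other)
        data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            return self._make(self.data * other, (self,), lambda g: (g * other,))
        other = self._lift(other)
        data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            return self * (1.0 / other)
        other = self._lift(other)
        data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(data, (self, other), backward)

    def __pow__(self, exponent: float):
        data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ np.expand_dims(g, -1), b.shape + (1,))[..., 0]
            elif a.ndim == 1:
                ga = (np.expand_dims(g, -2) @ np.swapaxes(b, -1, -2))[..., 0, :]
                ga = _unbroadcast(ga, a.shape)
                gb = np.expand_dims(a, -1) @ np.expand_dims(g, -2)
                gb = _unbroadcast(gb, b.shape)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (ga, gb)

        return self._make(data, (self, other), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(data, (self,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        return self._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inverse),))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)

        return self._make(out, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis with affine parameters."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = xhat * gamma.data + beta.data
        n = self.shape[-1]

        def backward(g):
            gy = g * gamma.data
            dx = inv * (
                gy
                - gy.mean(axis=-1, keepdims=True)
                - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
            )
            axes = tuple(range(g.ndim - 1))
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            return (dx, dgamma, dbeta)

        return self._make(out, (self, gamma, beta), backward)

    # -- spatial ops (NCHW) ------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None, padding: int | None = None):
        """2-D cross-correlation with zero padding ("same" when padding omitted).

        ``weight`` has shape (out_ch, in_ch, kh, kw); input is NCHW.
        """
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
        pad = (kh - 1) // 2 if padding is None else padding
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        # channels-last accumulation: one small GEMM per kernel offset avoids
        # materializing the full im2col tensor
        xpT = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # B,Hp,Wp,C
        y = np.zeros((B, Ho, Wo, O), dtype=x.dtype)
        wT = w.astype(x.dtype, copy=False)
        for i in range(kh):
            for j in range(kw):
                y += xpT[:, i : i + Ho, j : j + Wo, :] @ wT[:, :, i, j].T
        if bias is not None:
            y += bias.data
        out_data = np.ascontiguousarray(y.transpose(0, 3, 1, 2))

        def backward(g):
            gT = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # B,Ho,Wo,O
            gw = np.empty_like(w)
            gxpT = np.zeros_like(xpT)
            for i in range(kh):
                for j in range(kw):
                    patch = xpT[:, i : i + Ho, j : j + Wo, :]
                    gw[:, :, i, j] = np.tensordot(gT, patch, axes=([0, 1, 2], [0, 1, 2]))
                    gxpT[:, i : i + Ho, j : j + Wo, :] += gT @ wT[:, :, i, j]
            gxp = gxpT.transpose(0, 3, 1, 2)
            gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
            gx = np.ascontiguousarray(gx)
            grads = [gx, gw]
            if bias is not None:
                grads.append(g.sum(axis=(0, 2, 3)))
            return tuple(grads)

        prev = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, prev, backward)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor" | None = None):
        """Per-channel "same" 2-D cross-correlation; weight shape (C, kh, kw)."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError("depthwise weight channels must match input channels")
        pad = (kh - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
        y = np.einsum("bchwij,cij->bchw", cols, w, optimize=True)
        if bias is not None:
            y = y + bias.data[None, :, None, None]

        def backward(g):
            gw = np.einsum("bchwij,bchw->cij", cols, g, optimize=True)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + H, j : j + W] += g * w[None, :, i, j, None, None]
            gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
            grads = [gx, gw]
            if bias is not None:
                grads.append(g.sum(axis=(0, 2, 3)))
            return tuple(grads)

        prev = (self, weight) if bias is None else (self, weight, bias)
        return self._make(y, prev, backward)

    def avg_pool2d(self):
        """2x2 average pooling, stride 2, odd sizes handled by edge replication."""
        x = self.data
        B, C, H, W = x.shape
        ph, pw = H % 2, W % 2
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        y = 0.25 * (
            xp[:, :, 0::2, 0::2] + xp[:, :, 1::2, 0::2] + xp[:, :, 0::2, 1::2] + xp[:, :, 1::2, 1::2]
        )

        def backward(g):
            gp = np.zeros_like(xp)
            q = 0.25 * g
            gp[:, :, 0::2, 0::2] += q
            gp[:, :, 1::2, 0::2] += q
            gp[:, :, 0::2, 1::2] += q
            gp[:, :, 1::2, 1::2] += q
            gx = gp[:, :, :H, :W].copy()
            if ph:
                gx[:, :, H - 1, :] += gp[:, :, H, :W]
            if pw:
                gx[:, :, :, W - 1] += gp[:, :, :H, W]
            if ph and pw:
                gx[:, :, H - 1, W - 1] += gp[:, :, H, W]
            return (gx,)

        return self._make(y, (self,), backward)

    def upsample_bilinear(self, out_hw: tuple[int, int]):
        """Bilinear resize (align-corners convention) as two linear maps."""
        B, C, H, W = self.shape
        Ho, Wo = out_hw

        def interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
            R = np.zeros((n_out, n_in), dtype=dtype)
            if n_in == 1:
                R[:, 0] = 1.0
                return R
            src = np.linspace(0.0, n_in - 1.0, n_out)
            lo = np.clip(np.floor(src).astype(int), 0, n_in - 2)
            frac = src - lo
            R[np.arange(n_out), lo] = 1.0 - frac
            R[np.arange(n_out), lo + 1] = frac
            return R

        Ry = interp_matrix(Ho, H, self.dtype)
        Rx = interp_matrix(Wo, W, self.dtype)
        y = np.einsum("oh,bchw,pw->bcop", Ry, self.data, Rx, optimize=True)

        def backward(g):
            # dX[h,w] = sum_{o,p} Ry[o,h] g[o,p] Rx[p,w]
            return (np.einsum("oh,bcop,pw->bchw", Ry, g, Rx, optimize=True),)

        return self._make(y, (self,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(data)
    tracked = tuple(t for t in tensors if t.requires_grad or t._prev)
    if tracked:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = float(self.lr)  # plain float: numpy scalars would upcast float32 params
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
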
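"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based Tensor with the operations the package's attention and
convolution graphs need: broadcast-aware arithmetic, batched matmul,
reductions, shape ops (reshape/transpose/slice/concat/pad/roll), stable
softmax/log-softmax, elementwise nonlinearities, im2col convolution and
nearest-neighbour 2x upsampling.  Gradients accumulate on every tensor in
the graph, which keeps intermediate activations inspectable (Grad-CAM reads
them directly).  All math is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self.prev = _NoGrad._active
        _NoGrad._active = True

    def __exit__(self, *exc):
        _NoGrad._active = self.prev


def no_grad() -> _NoGrad:
    return _NoGrad()


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and not _NoGrad._active
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            self._accum(_sum_to_shape(g, self.data.shape))
            other._accum(_sum_to_shape(g, other.data.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            self._accum(_sum_to_shape(g * other.data, self.data.shape))
            other._accum(_sum_to_shape(g * self.data, other.data.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other._pow_const(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def _pow_const(self, p: float):
        out = self._make(self.data ** p, (self,), None)

        def backward(g):
            self._accum(_sum_to_shape(g * p * self.data ** (p - 1.0), self.data.shape))
        out._backward = backward
        return out

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        return self._pow_const(float(p))

    def matmul(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accum(_sum_to_shape(ga, a.shape))
            other._accum(_sum_to_shape(gb, b.shape))
        out._backward = backward
        return out

    __matmul__ = matmul

    # -- elementwise -------------------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        out = self._make(data, (self,), None)

        def backward(g):
            self._accum(g * data)
        out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            self._accum(g / self.data)
        out._backward = backward
        return out

    def sqrt(self):
        return self._pow_const(0.5)

    def tanh(self):
        data = np.tanh(self.data)
        out = self._make(data, (self,), None)

        def backward(g):
            self._accum(g * (1.0 - data ** 2))
        out._backward = backward
        return out

    def sigmoid(self):
        data = np.where(self.data >= 0,
                        1.0 / (1.0 + np.exp(-np.abs(self.data))),
                        np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = self._make(data, (self,), None)

        def backward(g):
            self._accum(g * data * (1.0 - data))
        out._backward = backward
        return out

    def softplus(self):
        # log(1 + e^x), overflow-safe
        data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = self._make(data, (self,), None)

        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-self.data.clip(-500, 500)))
            self._accum(g * sig)
        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def backward(g):
            self._accum(g * mask)
        out._backward = backward
        return out

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = self._make(x * phi, (self,), None)

        def backward(g):
            pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2 * np.pi)
            self._accum(g * (phi + x * pdf))
        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        out = self._make(data, (self,), None)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = self._make(data, (self,), None)

        def backward(g):
            gg = g
            dd = data
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
                dd = np.expand_dims(dd, axis)
            mask = self.data == dd
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None \
                else mask.sum()
            self._accum(mask * gg / counts)
        out._backward = backward
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)

        def backward(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)

        def backward(g):
            self._accum(g.transpose(inv))
        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = backward
        return out

    def pad(self, pad_width):
        out = self._make(np.pad(self.data, pad_width), (self,), None)

        def backward(g):
            slices = tuple(slice(p[0], p[0] + s)
                           for p, s in zip(pad_width, self.data.shape))
            self._accum(g[slices])
        out._backward = backward
        return out

    def roll(self, shift, axis):
        out = self._make(np.roll(self.data, shift, axis=axis), (self,), None)

        def backward(g):
            neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
            self._accum(np.roll(g, neg, axis=axis))
        out._backward = backward
        return out

    # -- composite math ----------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = self._make(y, (self,), None)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))
        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        ls = shifted - lse
        out = self._make(ls, (self,), None)

        def backward(g):
            soft = np.exp(ls)
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))
        out._backward = backward
        return out

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of the trailing two axes of (B, C, H, W)."""
        b, c, h, w = self.data.shape
        data = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        out = self._make(data, (self,), None)

        def backward(g):
            gg = g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
            self._accum(gg)
        out._backward = backward
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1):
        """2-D convolution via im2col.  Input (B, C, H, W), weight (O, C, kh, kw)."""
        x = self.data
        wgt = weight.data
        b_, c, h, w = x.shape
        o, c2, kh, kw = wgt.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
        eff_kh = (kh - 1) * dilation + 1
        eff_kw = (kw - 1) * dilation + 1
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (h + 2 * padding - eff_kh) // stride + 1
        ow = (w + 2 * padding - eff_kw) // stride + 1
        # im2col: (B, C, kh, kw, oh, ow)
        s0, s1, s2, s3 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp,
            shape=(b_, c, kh, kw, oh, ow),
            strides=(s0, s1, s2 * dilation, s3 * dilation, s2 * stride, s3 * stride),
            writeable=False,
        )
        cols2 = cols.reshape(b_, c * kh * kw, oh * ow)
        wf = wgt.reshape(o, c * kh * kw)
        out_data = np.einsum("ok,bkp->bop", wf, cols2).reshape(b_, o, oh, ow)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, o, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = self._make(out_data, parents, None)

        def backward(g):
            gf = g.reshape(b_, o, oh * ow)
            gw = np.einsum("bop,bkp->ok", gf, cols2).reshape(o, c, kh, kw)
            weight._accum(gw)
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            gcols = np.einsum("ok,bop->bkp", wf, gf).reshape(b_, c, kh, kw, oh, ow)
            gx = np.zeros_like(xp)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gx[:, :, hi:hi + oh * stride:stride,
                       wj:wj + ow * stride:stride] += gcols[:, :, i, j]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accum(gx)
        out._backward = backward
        return out

    def __repr__(self):
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    out = Tensor(out_data)
    if not _NoGrad._active and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])
        out._backward = backward
    return out
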
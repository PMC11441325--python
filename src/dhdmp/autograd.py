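"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is small (a few hundred thousand parameters at
desk scale) and built from a short list of dense-array primitives: matrix
products, slicing/gathering, concatenation, elementwise nonlinearities,
reductions, and a guarded power used for degree normalization.  This module
provides exactly those primitives as a :class:`Tensor` graph with reverse-mode
gradients, plus an Adam optimizer.

Design notes
------------
* Gradients accumulate in ``Tensor.grad`` (a numpy array of the tensor's
  shape) after :meth:`Tensor.backward` on a scalar.
* Broadcasting in ``+``/``*`` is supported; backward un-broadcasts by
  summing over broadcast axes.
* ``safe_pow(x, p)`` defines ``0**p := 0`` with zero gradient at 0, the
  pseudo-inverse convention used for zero node/hyperedge degrees.
* Arrays keep their floating dtype (float32 or float64); integer input is
  promoted to float64.  Determinism up to BLAS reduction order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "conv2d", "numerical_gradient"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
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
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # python scalars are "weak": don't promote a float32 tensor
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor(other) * self.pow(-1.0)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            ad, bd = a.data, b.data
            if ad.ndim == 1:
                ga = g @ np.swapaxes(bd, -1, -2) if bd.ndim > 1 else g * bd
            else:
                gb_t = np.swapaxes(bd, -1, -2) if bd.ndim > 1 else bd
                ga = g @ gb_t if bd.ndim > 1 else np.outer(g, bd)
            if bd.ndim == 1:
                gb = np.swapaxes(ad, -1, -2) @ g if ad.ndim > 1 else ad * g
            elif ad.ndim == 1:
                gb = np.outer(ad, g)
            elif ad.ndim > 2 and bd.ndim == 2:
                # stacked @ shared-matrix: accumulate over batch in one
                # flat product instead of a batched outer product
                k = ad.shape[-1]
                gb = ad.reshape(-1, k).T @ g.reshape(-1, g.shape[-1])
            else:
                gb = np.swapaxes(ad, -1, -2) @ g
            return (_unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape))

        return Tensor._make(out_data, (a, b), backward)

    def pow(self, p: float) -> "Tensor":
        out_data = self.data**p
        a = self

        def backward(g):
            return (g * p * a.data ** (p - 1.0),)

        return Tensor._make(out_data, (a,), backward)

    def safe_pow(self, p: float) -> "Tensor":
        """x**p where non-positive x maps to 0 with zero gradient.

        Used for D^{-1/2} / D^{-1} of degree matrices: zero degrees stay
        inert instead of producing infinities.
        """
        pos = self.data > 0
        out_data = np.where(pos, self.data, 1.0) ** p
        out_data[~pos] = 0.0
        a = self

        def backward(g):
            base = np.where(pos, a.data, 1.0)
            grad = g * p * base ** (p - 1.0)
            return (np.where(pos, grad, 0.0),)

        return Tensor._make(out_data, (a,), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        a = self
        return Tensor._make(np.log(self.data), (a,), lambda g: (g / a.data,))

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), (self,), lambda g: (np.where(mask, g, 0.0),)
        )

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)
        return Tensor._make(
            out_data, (self,), lambda g: (np.where(mask, g, slope * g),)
        )

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        a = self
        fancy = isinstance(idx, (np.ndarray, list)) or (
            isinstance(idx, tuple)
            and any(isinstance(i, (np.ndarray, list)) for i in idx)
        )

        def backward(g):
            grad = np.zeros_like(a.data)
            if fancy:
                np.add.at(grad, idx, g)
            else:
                grad[idx] += g
            return (grad,)

        return Tensor._make(self.data[idx], (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max-reduce along one axis; gradient flows to the first argmax."""
        a = self
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def backward(g):
            grad = np.zeros_like(a.data)
            g2 = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(grad, np.expand_dims(idx, axis), g2, axis)
            return (grad,)

        return Tensor._make(out_data, (a,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax (shift by the detached row max)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # -- backprop ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    # adopt the array unless it is the child's own grad
                    # buffer (e.g. both parents of `+` receive the same
                    # object); views of finalized child grads are safe
                    parent.grad = g.copy() if g is node.grad else g
                else:
                    parent.grad = parent.grad + g


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Valid 2-D convolution, stride 1: x (B,Cin,H,W), W (Cout,Cin,kh,kw).

    Implemented as one im2col matrix product so the graph holds a single
    node instead of a kernel-sized chain of slices.
    """
    B, cin, hh, ww = x.data.shape
    cout, cin_w, kh, kw = W.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel expects {cin_w}")
    hout, wout = hh - kh + 1, ww - kw + 1
    if hout < 1 or wout < 1:
        raise ValueError(f"input {hh}x{ww} too small for kernel {kh}x{kw}")
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * hout * wout, cin * kh * kw)
    wmat = W.data.reshape(cout, -1)
    out = (cols @ wmat.T + b.data).reshape(B, hout, wout, cout).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(B * hout * wout, cout)
        gw = (g2.T @ cols).reshape(W.data.shape)
        gb = g2.sum(axis=0)
        gcols = (g2 @ wmat).reshape(B, hout, wout, cin, kh, kw)
        gx = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + hout, j:j + wout] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        return gx, gw, gb

    return Tensor._make(out, (x, W, b), backward)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g**2
            m_hat = self._m[i] / (1 - b1**self.t)
            v_hat = self._v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar f at x; test utility."""
    x = x.astype(np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        grad[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
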
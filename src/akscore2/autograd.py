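"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph-attention networks need:
elementwise arithmetic with broadcasting, dense and sparse matrix
products (message passing uses constant scipy.sparse incidence
matrices), the usual activations, reductions, reshape and
concatenation.  Gradients are accumulated through a topologically
sorted tape; correctness is checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "as_tensor", "concat", "spmm", "no_grad",
           "set_default_dtype", "get_default_dtype", "default_dtype"]

_GRAD_ENABLED = True
_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float dtype for new tensors (float64 default; float32
    halves memory/bandwidth for desk-scale training runs)."""
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype.type


def get_default_dtype():
    return _DTYPE


class default_dtype:
    """Context manager scoping the tensor dtype (e.g. float32 runs)."""

    def __init__(self, dtype):
        self._dtype = dtype

    def __enter__(self):
        global _DTYPE
        self._prev = _DTYPE
        set_default_dtype(self._dtype)
        return self

    def __exit__(self, *exc):
        global _DTYPE
        _DTYPE = self._prev
        return False


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        if _GRAD_ENABLED:
            self._parents = parents
            self._backward = backward
        else:
            self._parents = ()
            self._backward = None
        self.requires_grad = requires_grad

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape),
                    _unbroadcast(grad, other.shape))

        return Tensor(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (_unbroadcast(grad * other.data, self.shape),
                    _unbroadcast(grad * self.data, other.shape))

        return Tensor(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (_unbroadcast(grad / other.data, self.shape),
                    _unbroadcast(-grad * self.data / other.data ** 2,
                                 other.shape))

        return Tensor(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (grad @ other.data.T, self.data.T @ grad)

        return Tensor(self.data @ other.data, (self, other), backward)

    def square(self):
        return Tensor(self.data ** 2, (self,), lambda g, out: (2.0 * g * self.data,))

    # -- activations ---------------------------------------------------
    def relu(self):
        return Tensor(np.maximum(self.data, 0.0), (self,),
                      lambda g, out: (g * (self.data > 0.0),))

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0.0, 1.0, alpha)
        return Tensor(np.where(self.data > 0.0, self.data, alpha * self.data),
                      (self,), lambda g, out: (g * slope,))

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid
        return Tensor(out_data, (self,),
                      lambda g, out: (g * out.data * (1.0 - out.data),))

    def softplus(self):
        # log(1 + e^x), stable for large |x|
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor(out_data, (self,), lambda g, out: (g * sig,))

    def exp(self):
        return Tensor(np.exp(self.data), (self,),
                      lambda g, out: (g * out.data,))

    def log(self):
        return Tensor(np.log(self.data), (self,),
                      lambda g, out: (g / self.data,))

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(grad, out):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return Tensor(self.data.reshape(*shape), (self,),
                      lambda g, out: (g.reshape(self.shape),))

    def take_rows(self, idx: np.ndarray):
        """Row gather (out[i] = self[idx[i]]); backward scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(grad, out):
            g = np.zeros_like(self.data)
            np.add.at(g, idx, grad)
            return (g,)

        return Tensor(self.data[idx], (self,), backward)

    # ------------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative DFS: a recursive closure would be a reference cycle
        # keeping the whole tape alive until the garbage collector runs
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, processed = stack.pop()
            if processed:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            grads = t._backward(t.grad, t)
            for parent, g in zip(t._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=parent.data.dtype,
                                           copy=True)
                    if parent.grad.shape != parent.data.shape:
                        parent.grad = np.broadcast_to(
                            parent.grad, parent.data.shape).copy()
                else:
                    parent.grad += g


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=_DTYPE), requires_grad=False)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad, out):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), backward)


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a tensor: out = M @ x.

    Used for edge gathers (E x N one-hot rows), scatter-sums (transpose)
    and mean pooling; the matrix itself is never differentiated.
    """
    x = as_tensor(x)

    def backward(grad, out):
        return (matrix.T @ grad,)

    return Tensor(matrix @ x.data, (x,), backward)
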
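"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records the operations applied to it; :func:`grad` walks the recorded graph
in reverse. Backward rules are themselves written in terms of Tensor
operations, so gradients can be differentiated again (``create_graph=True``)
— which is what the WGAN gradient penalty needs.

Only the operations the models in this package use are implemented.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "grad", "no_grad", "is_grad_enabled", "concat", "stack"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (eval / optimizer steps)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    return np.asarray(x, dtype=np.float64 if isinstance(x, float) else None)


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Tensor | None = None
        self._parents: tuple[Tensor, ...] = ()
        # maps upstream grad Tensor -> tuple of grad Tensors, one per parent
        self._backward: Callable[[Tensor], tuple] | None = None

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], tuple]) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _to_tensor(other)
        data = self.data + other.data
        return Tensor._make(data, (self, other), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = _to_tensor(other)
        data = self.data - other.data
        return Tensor._make(data, (self, other), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return _to_tensor(other).__sub__(self)

    def __mul__(self, other):
        other = _to_tensor(other)
        data = self.data * other.data
        return Tensor._make(data, (self, other), lambda g: (
            _unbroadcast(g * other, self.shape), _unbroadcast(g * self, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _to_tensor(other)
        data = self.data / other.data
        return Tensor._make(data, (self, other), lambda g: (
            _unbroadcast(g / other, self.shape),
            _unbroadcast(-g * self / (other * other), other.shape)))

    def __rtruediv__(self, other):
        return _to_tensor(other).__truediv__(self)

    def __pow__(self, p: float):
        assert np.isscalar(p)
        data = self.data ** p
        return Tensor._make(data, (self,), lambda g: (g * (self ** (p - 1)) * float(p),))

    def __matmul__(self, other):
        other = _to_tensor(other)
        data = self.data @ other.data
        a, b = self, other

        def backward(g: Tensor):
            ga = g @ b.swap_last_axes()
            gb = a.swap_last_axes() @ g
            return _unbroadcast_matmul(ga, a.shape), _unbroadcast_matmul(gb, b.shape)

        return Tensor._make(data, (a, b), backward)

    # -- elementwise functions --------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor._make(out_data, (self,), lambda g: (g * out,))
        return out

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        out = Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out,))
        return out

    def tanh(self):
        out_data = np.tanh(self.data)
        out = Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out * out),))
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(out_data, (self,), lambda g: (g * out * (1.0 - out),))
        return out

    def relu(self):
        mask = (self.data > 0).astype(self.data.dtype)
        mask_t = Tensor(mask)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask_t,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g: Tensor):
            if axis is None:
                return (g.reshape((1,) * len(shape)).broadcast_to(shape),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % len(shape) for a in axes)
            if not keepdims:
                kshape = tuple(1 if i in axes else s for i, s in enumerate(shape))
                g = g.reshape(kshape)
            return (g.broadcast_to(shape),)

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ---------------------------------------------------------

    def reshape(self, shape):
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def broadcast_to(self, shape):
        old = self.shape
        return Tensor._make(np.broadcast_to(self.data, shape).copy(), (self,),
                            lambda g: (_unbroadcast(g, old),))

    def swap_last_axes(self):
        """Transpose the trailing two axes (matmul backward helper)."""
        if self.ndim < 2:
            return self
        return self.swapaxes(-1, -2)

    def swapaxes(self, a: int, b: int):
        return Tensor._make(self.data.swapaxes(a, b), (self,),
                            lambda g: (g.swapaxes(a, b),))

    def transpose(self, axes):
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        shape = self.shape
        fancy = _is_fancy(idx)

        def backward(g: Tensor):
            def scatter(gd: np.ndarray) -> np.ndarray:
                z = np.zeros(shape, dtype=gd.dtype)
                if fancy:
                    np.add.at(z, idx, gd)  # duplicate indices must accumulate
                else:
                    z[idx] = gd
                return z
            return (_constant_map(g, scatter, lambda h: h[idx]),)

        return Tensor._make(self.data[idx], (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Gather rows along axis 0 with an integer index array (embedding lookup)."""
        idx = np.asarray(indices)
        shape = self.shape

        def backward(g: Tensor):
            def scatter(gd: np.ndarray) -> np.ndarray:
                z = np.zeros(shape, dtype=gd.dtype)
                np.add.at(z, idx.reshape(-1), gd.reshape(-1, shape[-1]))
                return z
            return (_constant_map(g, scatter, lambda h: h.take_rows(idx)),)

        return Tensor._make(self.data[idx], (self,), backward)


def _to_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_fancy(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, (np.ndarray, list)) for i in items)


def _constant_map(g: Tensor, fwd: Callable[[np.ndarray], np.ndarray],
                  lin_backward) -> Tensor:
    """Apply a linear index map to ``g`` keeping it differentiable.

    ``fwd`` is the data-level map; ``lin_backward`` its (linear) adjoint
    expressed with Tensor ops, so double backward stays available.
    """
    return Tensor._make(fwd(g.data), (g,), lambda h: (lin_backward(h),))


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _unbroadcast_matmul(g: Tensor, shape: tuple) -> Tensor:
    """Handle batched-matmul broadcasting over leading axes."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i in range(g.ndim - 2) if shape[i] == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_to_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Tensor):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._make(data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_to_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: Tensor):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = i
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._make(data, tensors, backward)


def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs: Iterable[Tensor],
         create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves
    differentiable nodes.
    """
    inputs = list(inputs)
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    grads: dict[int, Tensor] = {
        id(output): Tensor(np.ones_like(output.data))}
    owned: set[int] = set()

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(_topo_order(output)):
            g = grads.get(id(node))
            if g is None or node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                prev = grads.get(id(p))
                if prev is None:
                    grads[id(p)] = pg
                elif create_graph:
                    grads[id(p)] = prev + pg
                else:
                    # data-level accumulation, in place once we own the buffer
                    if id(p) not in owned:
                        prev = Tensor(prev.data + pg.data)
                        grads[id(p)] = prev
                        owned.add(id(p))
                    else:
                        np.add(prev.data, pg.data, out=prev.data)
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


def backward(loss: Tensor, params: Iterable[Tensor]) -> None:
    """Populate ``.grad`` on ``params`` (training convenience)."""
    params = list(params)
    gs = grad(loss, params, create_graph=False)
    for p, g in zip(params, gs):
        if p.grad is None:
            p.grad = g.detach()
        else:
            p.grad = Tensor(p.grad.data + g.data)
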
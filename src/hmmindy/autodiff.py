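"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations needed to differentiate an extended Kalman
filter with its covariance recursion kept inside the computation graph:
elementwise arithmetic with broadcasting, matrix products, ``tanh``,
transposes, reshapes, linear solves and a sum-of-squares reduction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "constant", "matmul", "tanh", "transpose", "reshape",
           "solve", "sumsq", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    grad = np.asarray(grad, dtype=np.float64)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the reverse-mode tape.

    Parameters
    ----------
    value : array_like
        The forward value (converted to float64).
    parents : tuple of Var
        Immediate inputs of the op that produced this node.
    bwd : callable or None
        Maps the output cotangent to a tuple of parent cotangents.
    requires_grad : bool
        Leaves with ``requires_grad=False`` are constants.
    """

    __slots__ = ("value", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, value, parents=(), bwd=None, requires_grad=True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self.bwd = bwd
        if parents:
            self.requires_grad = any(p.requires_grad for p in parents)
        else:
            self.requires_grad = requires_grad

    # -- operator sugar -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def T(self):
        return transpose(self)

    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _as_var(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.value, g * a.value))

    __rmul__ = __mul__

    def __neg__(self):
        return Var(-self.value, (self,), lambda g: (-g,))

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self):
        """Accumulate gradients of this (scalar) node into the tape."""
        order = _toposort(self)
        for node in order:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in order:
            if node.bwd is None or node.grad is None:
                continue
            gs = node.bwd(node.grad)
            for parent, g in zip(node.parents, gs):
                if not parent.requires_grad or g is None:
                    continue
                g = _unbroadcast(g, parent.value.shape)
                parent.grad = g if parent.grad is None else parent.grad + g


def _as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x, requires_grad=False)


def constant(x) -> Var:
    return Var(x, requires_grad=False)


def _binary(a, b, fwd, make_bwd) -> Var:
    a, b = _as_var(a), _as_var(b)
    return Var(fwd(a.value, b.value), (a, b),
               lambda g: make_bwd(g, a, b))


def matmul(a, b) -> Var:
    a, b = _as_var(a), _as_var(b)

    def bwd(g):
        return (g @ b.value.T, a.value.T @ g)

    return Var(a.value @ b.value, (a, b), bwd)


def tanh(a) -> Var:
    a = _as_var(a)
    out = np.tanh(a.value)
    return Var(out, (a,), lambda g: (g * (1.0 - out * out),))


def transpose(a) -> Var:
    a = _as_var(a)
    return Var(a.value.T, (a,), lambda g: (g.T,))


def reshape(a, shape) -> Var:
    a = _as_var(a)
    old = a.value.shape
    return Var(a.value.reshape(shape), (a,), lambda g: (g.reshape(old),))


def solve(a, b) -> Var:
    """X = A^{-1} B with the standard adjoint rules."""
    a, b = _as_var(a), _as_var(b)
    x = np.linalg.solve(a.value, b.value)

    def bwd(g):
        gb = np.linalg.solve(a.value.T, g)
        ga = -gb @ x.T
        return (ga, gb)

    return Var(x, (a, b), bwd)


def sumsq(a) -> Var:
    a = _as_var(a)
    return Var(np.sum(a.value * a.value), (a,), lambda g: (2.0 * g * a.value,))


def _toposort(root: Var):
    """Reverse topological order (root first), iterative."""
    order, visited, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in visited:
                stack.append((p, False))
    return order[::-1]


def grad_check(fn, args, eps=1e-6):
    """Central finite differences of scalar `fn(*args)` w.r.t. each array.

    Returns (analytic, numeric) gradient lists. Used by the test suite to
    validate both the tape and hand-derived adjoints.
    """
    leaves = [Var(np.asarray(a, dtype=np.float64)) for a in args]
    out = fn(*leaves)
    out.backward()
    analytic = [leaf.grad if leaf.grad is not None else np.zeros_like(leaf.value)
                for leaf in leaves]
    numeric = []
    for k, a in enumerate(args):
        a = np.asarray(a, dtype=np.float64)
        g = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            pert = [np.array(x, dtype=np.float64) for x in args]
            pert[k][idx] += eps
            hi = fn(*[constant(x) for x in pert]).value
            pert[k][idx] -= 2 * eps
            lo = fn(*[constant(x) for x in pert]).value
            g[idx] = (hi - lo) / (2 * eps)
            it.iternext()
        numeric.append(g)
    return analytic, numeric
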
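"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the mesh-deformation network and its loss
terms need: broadcasting arithmetic, matmul, reductions with argmax-routing,
gather/scatter indexing, sparse-operator products, 3-D convolution, 2x max
pooling and differentiable trilinear grid sampling.  Floating dtypes are
preserved (float64 in -> float64 math, so analytic oracles can be matched to
tight tolerances; float32 models run at single precision for speed).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "astensor",
    "parameter",
    "concatenate",
    "stack",
    "spmm",
    "conv3d",
    "maxpool2",
    "trilinear_sample",
    "leaky_relu",
    "clip_grad_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad=False, parents=(), backward=None):
        value = np.asarray(value)
        if not np.issubdtype(value.dtype, np.floating):
            value = value.astype(np.float64)
        self.value = value
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self):
        return Tensor(self.value.copy())

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` into every reachable parent."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without grad requires a scalar Tensor")
            grad = np.ones_like(self.value)
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
        self.grad = np.asarray(grad, dtype=self.value.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        # out-of-place accumulation everywhere -> storing g unaliased is safe
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def _scalar_op(self, value, dself):
        """Elementwise op with a python scalar (keeps dtype, NEP-50 style)."""
        out = Tensor(value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * dself if dself != 1 else g)

        out._backward = bw
        return out

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.value + other, 1)
        other = astensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.value - other, 1)
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.value * other, other)
        other = astensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.value / other, 1.0 / other)
        other = astensor(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.value / other.value**2, other.value.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.value**exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.value ** (exponent - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        out._backward = bw
        return out

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.value.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.value.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.value.transpose(axes), parents=(self,))
        inv = np.argsort(axes) if axes else None

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.value)
                np.add.at(acc, idx, g)
                self._accum(acc)

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if self.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.value.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def _extremum(self, axis, mode):
        fn = np.argmax if mode == "max" else np.argmin
        idx = fn(self.value, axis=axis)
        val = np.take_along_axis(self.value, np.expand_dims(idx, axis), axis=axis)
        out = Tensor(np.squeeze(val, axis=axis), parents=(self,))

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.value)
                np.put_along_axis(
                    acc, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
                )
                self._accum(acc)

        out._backward = bw
        return out

    def max(self, axis):
        return self._extremum(axis, "max")

    def min(self, axis):
        return self._extremum(axis, "min")

    # -- elementwise functions ------------------------------------------------
    def sqrt(self):
        out = Tensor(np.sqrt(self.value), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.sqrt(self.value))

        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.value), parents=(self,))
        s = np.sign(self.value)

        def bw(g):
            if self.requires_grad:
                self._accum(g * s)

        out._backward = bw
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value, dtype=np.float64) -> Tensor:
    return Tensor(np.array(value, dtype=dtype), requires_grad=True)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.stack([t.value for t in tensors], axis=axis), parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def spmm(op: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse operator times dense tensor; the operator is a constant."""
    x = astensor(x)
    out = Tensor(op @ x.value, parents=(x,))
    opT = op.T.tocsr()

    def bw(g):
        if x.requires_grad:
            x._accum(opT @ g)

    out._backward = bw
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = astensor(x)
    mask = np.where(x.value > 0, 1.0, slope).astype(x.value.dtype)
    out = Tensor(x.value * mask, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = bw
    return out


# -- convolutional primitives ------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) columns ordered (C, kx, ky, kz).

    Works channels-last internally so the window-view flattening copy is
    cache-friendly (the channel axis is contiguous).
    """
    p = k // 2
    xcl = np.ascontiguousarray(np.moveaxis(x, 0, -1))
    xp = np.pad(xcl, ((p, p), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(0, 1, 2))
    d, h, w = win.shape[:3]
    return win.reshape(d * h * w, -1)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded stride-1 3-D convolution (cross-correlation).

    x: (C_in, D, H, W); weight: (C_out, C_in, k, k, k); bias: (C_out,).
    """
    x, weight, bias = astensor(x), astensor(weight), astensor(bias)
    co, ci, k = weight.shape[0], weight.shape[1], weight.shape[2]
    _, d, h, w = x.shape
    cols = _im2col(x.value, k)
    out2d = cols @ weight.value.reshape(co, -1).T + bias.value
    out = Tensor(
        np.moveaxis(out2d.reshape(d, h, w, co), -1, 0),
        parents=(x, weight, bias),
    )

    def bw(g):
        g2d = np.moveaxis(g, 0, -1).reshape(-1, co)
        if bias.requires_grad:
            bias._accum(g2d.sum(axis=0))
        if weight.requires_grad:
            weight._accum((g2d.T @ cols).reshape(weight.value.shape))
        if x.requires_grad:
            # full correlation of the output gradient with the flipped kernel
            wflip = weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            gcols = _im2col(g, k)
            dx2d = gcols @ wflip.reshape(ci, -1).T
            x._accum(np.moveaxis(dx2d.reshape(d, h, w, ci), -1, 0))

    out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2 on a (C, D, H, W) tensor."""
    x = astensor(x)
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    blocks = (
        x.value.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, -1, 8)
    )
    idx = blocks.argmax(axis=2)
    val = np.take_along_axis(blocks, idx[:, :, None], axis=2)[:, :, 0]
    out = Tensor(val.reshape(c, d // 2, h // 2, w // 2), parents=(x,))

    def bw(g):
        if x.requires_grad:
            acc = np.zeros((c, blocks.shape[1], 8))
            np.put_along_axis(acc, idx[:, :, None], g.reshape(c, -1, 1), axis=2)
            acc = (
                acc.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(c, d, h, w)
            )
            x._accum(acc)

    out._backward = bw
    return out


def trilinear_sample(grid, points: Tensor) -> Tensor:
    """Differentiable trilinear sampling of a (C, D, H, W) grid at K points.

    ``points`` are (K, 3) continuous grid indices; coordinates outside the
    grid are clamped to the boundary (zero positional gradient there).
    """
    points = astensor(points)
    grid_t = grid if isinstance(grid, Tensor) else None
    gv = grid.value if grid_t is not None else np.asarray(grid)
    c, d, h, w = gv.shape
    dims = np.array([d, h, w], dtype=points.value.dtype)
    p = np.clip(points.value, 0.0, dims - 1.0)
    inside = (points.value > 0.0) & (points.value < dims - 1.0)
    i0 = np.floor(np.clip(p, 0, dims - 2)).astype(np.int64)
    f = p - i0  # fractional part in [0, 1]
    i1 = i0 + 1

    corners = []  # (K, C) value at each of the 8 corners
    weights = []
    dwx, dwy, dwz = [], [], []
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    for bx in (0, 1):
        wx, gx = (fx, 1.0) if bx else (1.0 - fx, -1.0)
        ix = i1[:, 0] if bx else i0[:, 0]
        for by in (0, 1):
            wy, gy = (fy, 1.0) if by else (1.0 - fy, -1.0)
            iy = i1[:, 1] if by else i0[:, 1]
            for bz in (0, 1):
                wz, gz = (fz, 1.0) if bz else (1.0 - fz, -1.0)
                iz = i1[:, 2] if bz else i0[:, 2]
                corners.append((ix, iy, iz, gv[:, ix, iy, iz].T))
                weights.append(wx * wy * wz)
                dwx.append(gx * wy * wz)
                dwy.append(wx * gy * wz)
                dwz.append(wx * wy * gz)

    val = np.zeros((p.shape[0], c), dtype=np.result_type(gv, p))
    for (_, _, _, cv), wgt in zip(corners, weights):
        val += cv * wgt[:, None]
    parents = (points,) if grid_t is None else (points, grid_t)
    out = Tensor(val, parents=parents)

    def bw(g):
        if points.requires_grad:
            dp = np.zeros_like(points.value)
            for (_, _, _, cv), gx_, gy_, gz_ in zip(corners, dwx, dwy, dwz):
                contrib = (g * cv).sum(axis=1)
                dp[:, 0] += contrib * gx_
                dp[:, 1] += contrib * gy_
                dp[:, 2] += contrib * gz_
            dp *= inside  # clamped coordinates get zero positional gradient
            points._accum(dp)
        if grid_t is not None and grid_t.requires_grad:
            dg = np.zeros_like(gv)
            for (ix, iy, iz, _), wgt in zip(corners, weights):
                np.add.at(
                    dg.transpose(1, 2, 3, 0), (ix, iy, iz), g * wgt[:, None]
                )
            grid_t._accum(dg)

    out._backward = bw
    return out


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(
        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
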
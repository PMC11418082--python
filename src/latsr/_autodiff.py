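"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package needs gradients in three places: training the masked autoregressive
flow (gradients w.r.t. flow parameters), evaluating the flow-density prior
inside the latent search (gradients w.r.t. the style vector), and the latent
search itself (gradients of the full objective w.r.t. the extended latent
through the synthesis network and the degradation operator).  A small tape
based engine covers all three with one code path; gradient correctness is
pinned by central finite-difference tests.

Only the handful of primitives the package composes are implemented: broadcast
arithmetic, 2-D matmul, elementwise nonlinearities, reductions with axis /
keepdims, reshape / flip, a 3x3 zero-padded convolution, nearest 2x upsampling
and a separable linear-operator application (M_h @ X @ M_w^T per channel).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array plus the tape needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._prev: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def needs_grad(self) -> bool:
        return self.requires_grad or bool(self._prev)

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def item(self) -> float:
        return float(self.data)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.needs_grad for p in prev):
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this (scalar or array) tensor, seeding with ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if not t.needs_grad:
            return
        if t.grad is None:
            t.grad = g.copy()
        else:
            t.grad = t.grad + g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bwd(g):
            Tensor._accum(a, _unbroadcast(g, a.data.shape))
            Tensor._accum(b, _unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bwd(g):
            Tensor._accum(a, _unbroadcast(g * b.data, a.data.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def bwd(g):
            Tensor._accum(a, -g)

        return self._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        a = self

        def bwd(g):
            Tensor._accum(a, g * p * np.power(a.data, p - 1.0))

        return self._make(np.power(a.data, p), (a,), bwd)

    def __pow__(self, p):
        return self.pow(float(p))

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bwd(g):
            Tensor._accum(a, g @ b.data.T)
            Tensor._accum(b, a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), bwd)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            Tensor._accum(a, g * out_data)

        return self._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            Tensor._accum(a, g / a.data)

        return self._make(np.log(a.data), (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            Tensor._accum(a, g * (1.0 - out_data * out_data))

        return self._make(out_data, (a,), bwd)

    def abs(self):
        a = self

        def bwd(g):
            # subgradient sign(0) = 0
            Tensor._accum(a, g * np.sign(a.data))

        return self._make(np.abs(a.data), (a,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        factor = np.where(mask, 1.0, slope)

        def bwd(g):
            Tensor._accum(a, g * factor)

        return self._make(a.data * factor, (a,), bwd)

    def relu(self):
        return self.leaky_relu(0.0)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                Tensor._accum(a, np.broadcast_to(g, a.data.shape).copy())
                return
            g2 = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.data.ndim for ax in axes):
                    g2 = np.expand_dims(g2, ax)
            Tensor._accum(a, np.broadcast_to(g2, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = a.data.shape

        def bwd(g):
            Tensor._accum(a, g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), bwd)

    def flip(self, axis: int = -1):
        a = self

        def bwd(g):
            Tensor._accum(a, np.flip(g, axis=axis))

        return self._make(np.flip(a.data, axis=axis), (a,), bwd)

    # -- structured primitives -------------------------------------------
    def conv3x3(self, w: "Tensor"):
        """3x3 convolution with zero padding 1.

        ``self``: (C_in, H, W); ``w``: (C_out, C_in, 3, 3) -> (C_out, H, W).
        """
        x, w = self, Tensor.as_tensor(w)
        c_in, h, wd = x.data.shape
        c_out = w.data.shape[0]
        xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # (C_in, H, W, 3, 3) -> (H*W, C_in*9)
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, c_in * 9)
        wmat = w.data.reshape(c_out, c_in * 9)
        out = (cols @ wmat.T).T.reshape(c_out, h, wd)

        def bwd(g):
            gmat = g.reshape(c_out, h * wd).T  # (H*W, C_out)
            if w.needs_grad:
                Tensor._accum(w, (gmat.T @ cols).reshape(w.data.shape))
            if x.needs_grad:
                dcols = (gmat @ wmat).reshape(h, wd, c_in, 3, 3)
                dxp = np.zeros_like(xp)
                for di in range(3):
                    for dj in range(3):
                        dxp[:, di:di + h, dj:dj + wd] += dcols[:, :, :, di, dj].transpose(2, 0, 1)
                Tensor._accum(x, dxp[:, 1:-1, 1:-1])

        return self._make(out, (x, w), bwd)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of a (C, H, W) tensor."""
        a = self
        c, h, w = a.data.shape

        def bwd(g):
            Tensor._accum(a, g.reshape(c, h, 2, w, 2).sum(axis=(2, 4)))

        return self._make(a.data.repeat(2, axis=1).repeat(2, axis=2), (a,), bwd)

    def sep_apply(self, mh: np.ndarray, mw: np.ndarray):
        """Apply a separable linear operator per channel: Y_c = mh @ X_c @ mw.T.

        ``mh``/``mw`` are constant matrices (e.g. antialiased bicubic
        downscaling or Gaussian blur factors); input is (C, H, W).
        """
        a = self
        mh = np.asarray(mh, dtype=np.float64)
        mw = np.asarray(mw, dtype=np.float64)
        out = np.einsum("ij,cjk,lk->cil", mh, a.data, mw, optimize=True)

        def bwd(g):
            Tensor._accum(a, np.einsum("ji,cjk,kl->cil", mh, g, mw, optimize=True))

        return self._make(out, (a,), bwd)


def _interp_with_slopes(r, knots_x, knots_y):
    """Piecewise-linear interpolation with linear end extrapolation.

    Returns (values, local slopes)."""
    idx = np.clip(np.searchsorted(knots_x, r) - 1, 0, len(knots_x) - 2)
    x0, x1 = knots_x[idx], knots_x[idx + 1]
    y0, y1 = knots_y[idx], knots_y[idx + 1]
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (r - x0), slope


def radial_quantile_map(u: "Tensor", knots_r: np.ndarray, knots_t: np.ndarray):
    """Monotone radial rescaling v = u * s(r)/r with r = |u| per row.

    ``s`` is the piecewise-linear map through (knots_r, knots_t) (linearly
    extrapolated); returns (v, per-row log |det J|) with
    log|det| = log s'(r) + (d-1) (log s(r) - log r).
    """
    u = Tensor.as_tensor(u)
    n, d = u.data.shape
    r = np.sqrt(np.sum(u.data**2, axis=1))
    r = np.maximum(r, 1e-12)
    s, sp = _interp_with_slopes(r, knots_r, knots_t)
    s = np.maximum(s, 1e-12)
    g = s / r
    v_data = u.data * g[:, None]
    logdet_data = np.log(sp) + (d - 1) * (np.log(s) - np.log(r))

    out_v = Tensor(v_data)
    out_l = Tensor(logdet_data)

    def bwd_v(gv):
        dot = np.sum(gv * u.data, axis=1)
        Tensor._accum(u, gv * g[:, None]
                      + u.data * (dot * (sp - g) / r**2)[:, None])

    def bwd_l(gl):
        coef = (d - 1) * (sp / s - 1.0 / r) / r
        Tensor._accum(u, u.data * (gl * coef)[:, None])

    if u.needs_grad:
        out_v._prev, out_v._backward = (u,), bwd_v
        out_l._prev, out_l._backward = (u,), bwd_l
    return out_v, out_l


def radial_quantile_inverse(v: np.ndarray, knots_r: np.ndarray,
                            knots_t: np.ndarray) -> np.ndarray:
    """Invert ``radial_quantile_map`` (numpy path)."""
    rp = np.maximum(np.sqrt(np.sum(v**2, axis=1)), 1e-12)
    r, _ = _interp_with_slopes(rp, knots_t, knots_r)
    return v * (np.maximum(r, 1e-12) / rp)[:, None]


class Adam:
    """Adaptive-moment gradient descent over a list of leaf Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None, grad_clip: float | None = None) -> None:
        """Take one step using each parameter's accumulated ``.grad``."""
        lr = self.lr if lr is None else lr
        self.t += 1
        if grad_clip is not None:
            total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params if p.grad is not None))
            scale = 1.0 if total <= grad_clip else grad_clip / (total + 1e-12)
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None
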
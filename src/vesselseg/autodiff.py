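"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set needed by the segmentation network and its
training objectives: elementwise arithmetic, reductions, sigmoid/ReLU, 3D
convolution, 2x max-pooling, separable linear/nearest resampling, channel
concatenation, batch normalisation, and a trilinear backward warp that is
differentiable with respect to the sampled image.

Tensors are plain wrappers around ``numpy.ndarray`` with a ``grad`` slot and a
closure-based backward pass over a topologically sorted tape.  The engine is
dtype-agnostic (float32 for network training, float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                if p.grad is None:
                    p.grad = g.astype(p.data.dtype, copy=True)
                else:
                    p.grad += g

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        return self._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        return self._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        inv = 1.0 / other.data
        return self._make(
            self.data * inv,
            (self, other),
            lambda g: (
                _unbroadcast(g * inv, self.shape),
                _unbroadcast(-g * self.data * inv * inv, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = np.power(self.data, e)

        def backward(g):
            base = np.where(self.data == 0, 1.0, self.data)
            return (g * e * out_data / base,)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self):
        return self._make(
            self.data.sum(), (self,), lambda g: (np.broadcast_to(g, self.shape),)
        )

    def mean(self):
        n = self.data.size
        return self._make(
            self.data.mean(),
            (self,),
            lambda g: (np.broadcast_to(g / n, self.shape),),
        )

    # -- activations ----------------------------------------------------------
    def sigmoid(self):
        z = np.clip(self.data, -60.0, 60.0)  # avoid overflow in exp
        s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# Structured operators (N, C, X, Y, Z layout)
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D cross-correlation with 'same' padding (odd kernels only).

    ``x``: (N, C, X, Y, Z); ``w``: (O, C, k, k, k); ``b``: (O,).
    Computed as a sum of channel matmuls over the k^3 kernel offsets, which
    keeps memory traffic contiguous (no im2col gather).
    """
    N, C, X, Y, Z = x.shape
    O, C2, k, _, _ = w.shape
    if C2 != C:
        raise ValueError(f"channel mismatch: input {C}, weight {C2}")
    p = k // 2
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        if p
        else x.data
    )
    Xp, Yp, Zp = xp.shape[2:]
    xpf = xp.reshape(N, C, Xp * Yp * Zp)  # contiguous, reshape is free
    out = np.zeros((N, O, X, Y, Z), dtype=x.data.dtype)
    # matmul once per offset over the full padded volume (contiguous),
    # then accumulate the shifted window of the result
    for i in range(k):
        for j in range(k):
            for l in range(k):
                z = (w.data[:, :, i, j, l] @ xpf).reshape(N, O, Xp, Yp, Zp)
                out += z[:, :, i : i + X, j : j + Y, l : l + Z]
    out += b.data.reshape(1, O, 1, 1, 1)

    def backward(g):
        grad_w = np.empty_like(w.data)
        grad_b = g.sum(axis=(0, 2, 3, 4))
        # pad the output gradient so the input-gradient pass is the mirrored
        # correlation with flipped offsets, again matmul-on-contiguous
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else g
        gpf = np.ascontiguousarray(gp).reshape(N, O, -1)
        gx = np.zeros_like(x.data)
        wt = w.data.transpose(1, 0, 2, 3, 4)  # C,O,k,k,k
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + X, j : j + Y, l : l + Z]
                    grad_w[:, :, i, j, l] = np.tensordot(
                        g, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
                    z = (wt[:, :, i, j, l] @ gpf).reshape(N, C, Xp, Yp, Zp)
                    ri, rj, rl = k - 1 - i, k - 1 - j, k - 1 - l
                    gx += z[:, :, ri : ri + X, rj : rj + Y, rl : rl + Z]
        return gx, grad_w, grad_b

    return Tensor(0.0)._make(out, (x, w, b), backward)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    N, C, X, Y, Z = x.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"maxpool3d needs even spatial dims, got {(X, Y, Z)}")
    r = x.data.reshape(N, C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, X // 2, Y // 2, Z // 2, 8)
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((N, C, X // 2, Y // 2, Z // 2, 8), dtype=g.dtype)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(N, C, X // 2, Y // 2, Z // 2, 2, 2, 2)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, X, Y, Z)
        return (gr,)

    return Tensor(0.0)._make(out, (x,), backward)


def _resize_matrix(n_in: int, n_out: int, mode: str, dtype) -> np.ndarray:
    """(n_out, n_in) interpolation matrix, align_corners=False convention."""
    A = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    if mode == "nearest":
        idx = np.clip(np.floor((np.arange(n_out) + 0.5) * scale), 0, n_in - 1)
        A[np.arange(n_out), idx.astype(int)] = 1.0
    else:
        i0 = np.clip(np.floor(src), 0, n_in - 1).astype(int)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        w = np.clip(src - i0, 0.0, 1.0)
        A[np.arange(n_out), i0] += 1.0 - w
        A[np.arange(n_out), i1] += w
    return A


def resize3d(x: Tensor, out_shape, mode: str = "linear") -> Tensor:
    """Separable spatial resampling of (N, C, X, Y, Z) to ``out_shape``."""
    mats = [
        _resize_matrix(s_in, s_out, mode, x.data.dtype)
        for s_in, s_out in zip(x.shape[2:], out_shape)
    ]

    def apply(data, matrices):
        for axis, A in zip((2, 3, 4), matrices):
            data = np.moveaxis(np.tensordot(data, A, axes=([axis], [1])), -1, axis)
        return data

    out = apply(x.data, mats)

    def backward(g):
        return (apply(g, [A.T for A in mats]),)

    return Tensor(0.0)._make(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return Tensor(0.0)._make(
        out, (a, b), lambda g: (g[:, :ca], g[:, ca:])
    )


def batchnorm3d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation; running stats are updated in place."""
    axes = (0, 2, 3, 4)
    shape = (1, x.shape[1], 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    n = x.data.size // x.shape[1]

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gamma.data.reshape(shape)
        if training:
            dx = (
                dxhat
                - dxhat.mean(axis=axes).reshape(shape)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape) / n
            ) * inv_std.reshape(shape)
        else:
            dx = dxhat * inv_std.reshape(shape)
        return dx, dgamma, dbeta

    return Tensor(0.0)._make(out, (x, gamma, beta), backward)


def warp_trilinear(x: Tensor, coords: np.ndarray) -> Tensor:
    """Backward warp: sample ``x`` at absolute voxel positions ``coords``.

    ``x``: (N, C, X, Y, Z); ``coords``: (N, 3, X, Y, Z) in voxel units.
    Out-of-bounds positions read as 0.  Differentiable w.r.t. ``x`` only
    (``coords`` is a fixed, randomly sampled deformation).
    """
    N, C, X, Y, Z = x.shape
    dims = np.array([X, Y, Z])
    c = coords.reshape(N, 3, -1)  # N,3,V
    V = c.shape[-1]
    i0 = np.floor(c).astype(np.int64)
    frac = (c - i0).astype(x.data.dtype)

    corners = []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                off = np.array([dx, dy, dz]).reshape(1, 3, 1)
                idx = i0 + off
                valid = np.all((idx >= 0) & (idx < dims.reshape(1, 3, 1)), axis=1)
                w = np.prod(
                    np.where(off == 1, frac, 1.0 - frac), axis=1
                ) * valid.astype(x.data.dtype)
                idxc = np.clip(idx, 0, (dims - 1).reshape(1, 3, 1))
                flat = (idxc[:, 0] * Y + idxc[:, 1]) * Z + idxc[:, 2]  # N,V
                corners.append((flat, w))

    xflat = x.data.reshape(N, C, -1)
    out = np.zeros((N, C, V), dtype=x.data.dtype)
    for flat, w in corners:
        out += np.take_along_axis(xflat, flat[:, None, :], axis=2) * w[:, None, :]
    out = out.reshape(N, C, X, Y, Z)

    def backward(g):
        gflat = g.reshape(N, C, -1)
        gx = np.zeros((N, C, X * Y * Z), dtype=g.dtype)
        for flat, w in corners:
            contrib = gflat * w[:, None, :]
            for n in range(N):
                for ch in range(C):
                    np.add.at(gx[n, ch], flat[n], contrib[n, ch])
        return (gx.reshape(N, C, X, Y, Z),)

    return Tensor(0.0)._make(out, (x,), backward)


def slice_batch(x: Tensor, i: int) -> Tensor:
    """Select sample ``i`` of a batched tensor, keeping the batch axis."""

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[i : i + 1] = g
        return (gx,)

    return Tensor(0.0)._make(x.data[i : i + 1], (x,), backward)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
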
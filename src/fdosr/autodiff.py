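"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its networks with plain numpy, so this module provides
the small set of differentiable operations the architecture needs: 3D
convolution (stride 1, zero-padded "same"), ReLU, elementwise add, channel
concatenation, per-voxel linear maps, separable trilinear resizing, and
the two loss reductions (mean absolute error and the masked
frequency-domain L1).  Each operation builds a node on a tape;
``backward`` runs the reverse sweep over the topologically sorted graph.

Arrays are channels-first: features are ``(C, D, H, W)``.
"""
from __future__ import annotations

import numpy as np

from .resample import linear_axis_matrix

__all__ = [
    "Var",
    "backward",
    "conv3d",
    "relu",
    "add",
    "concat_channels",
    "pointwise_linear",
    "resize_linear_nd",
    "mean_abs_error",
    "masked_spectral_l1",
    "add_scaled",
]


class Var:
    """A tape node: a value, an accumulated gradient, and a backward rule."""

    __slots__ = ("value", "grad", "parents", "_bwd", "name")

    def __init__(self, value, parents=(), bwd=None, name: str | None = None):
        self.value = np.asarray(value)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Var, ...] = tuple(parents)
        self._bwd = bwd
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None


def _topo_order(root: Var) -> list[Var]:
    order: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def backward(root: Var) -> None:
    """Accumulate d(root)/d(node) into ``node.grad`` for every reachable node."""
    if root.value.ndim != 0:
        raise ValueError("backward expects a scalar root")
    order = _topo_order(root)
    root.grad = np.asarray(1.0, dtype=root.value.dtype)
    for node in reversed(order):
        if node._bwd is None or node.grad is None:
            continue
        grads = node._bwd(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None:
                continue
            parent.grad = g if parent.grad is None else parent.grad + g


# ---------------------------------------------------------------------------
# differentiable operations


def _conv3d_value(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 zero-padded 'same' correlation as a sum of shifted GEMMs."""
    c_in, d, h, wd = x.shape
    c_out = w.shape[0]
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.zeros((c_out, d * h * wd), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, i : i + d, j : j + h, l : l + wd].reshape(c_in, -1)
                out += w[:, :, i, j, l] @ xs
    out = out.reshape(c_out, d, h, wd)
    if b is not None:
        out += b[:, None, None, None]
    return out


def conv3d(x: Var, w: Var, b: Var | None = None) -> Var:
    """3D convolution (cross-correlation), stride 1, zero-padded to keep dims.

    ``x`` is ``(C_in, D, H, W)``, ``w`` is ``(C_out, C_in, k, k, k)`` with odd
    ``k``, ``b`` is ``(C_out,)``.
    """
    if w.value.ndim != 5 or w.value.shape[2] % 2 == 0:
        raise ValueError("conv3d expects (C_out, C_in, k, k, k) weights with odd k")
    if x.value.shape[0] != w.value.shape[1]:
        raise ValueError(
            f"input channels {x.value.shape[0]} do not match weight {w.value.shape[1]}"
        )
    val = _conv3d_value(x.value, w.value, None if b is None else b.value)
    c_in, d, h, wd = x.value.shape
    k = w.value.shape[2]
    p = k // 2

    def bwd(g):
        g = np.ascontiguousarray(g)
        gflat = g.reshape(g.shape[0], -1)
        # grad wrt input: accumulate transposed GEMMs back into padded buffer
        dxp = np.zeros((c_in, d + 2 * p, h + 2 * p, wd + 2 * p), dtype=g.dtype)
        xp = np.pad(x.value, ((0, 0), (p, p), (p, p), (p, p)))
        dw = np.empty_like(w.value)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, i : i + d, j : j + h, l : l + wd].reshape(c_in, -1)
                    dw[:, :, i, j, l] = gflat @ xs.T
                    dxp[:, i : i + d, j : j + h, l : l + wd] += (
                        w.value[:, :, i, j, l].T @ gflat
                    ).reshape(c_in, d, h, wd)
        dx = dxp[:, p : p + d, p : p + h, p : p + wd]
        db = None if b is None else gflat.sum(axis=1)
        return (dx, dw, db)

    parents = (x, w) if b is None else (x, w, b)
    return Var(val, parents, bwd, name="conv3d")


def relu(x: Var) -> Var:
    val = np.maximum(x.value, 0)

    def bwd(g):
        return (g * (x.value > 0),)

    return Var(val, (x,), bwd, name="relu")


def add(a: Var, b: Var) -> Var:
    if a.value.shape != b.value.shape:
        raise ValueError(f"add shape mismatch: {a.value.shape} vs {b.value.shape}")
    return Var(a.value + b.value, (a, b), lambda g: (g, g), name="add")


def concat_channels(parts: list[Var]) -> Var:
    val = np.concatenate([p.value for p in parts], axis=0)
    sizes = [p.value.shape[0] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=0))

    return Var(val, tuple(parts), bwd, name="concat")


def pointwise_linear(x: Var, w: Var, b: Var) -> Var:
    """Shared linear map over the channel axis: (C_in, ...) -> (C_out, ...)."""
    c_in = x.value.shape[0]
    if w.value.shape[1] != c_in:
        raise ValueError(
            f"feature width {c_in} does not match linear layer input {w.value.shape[1]}"
        )
    spatial = x.value.shape[1:]
    xf = x.value.reshape(c_in, -1)
    val = (w.value @ xf + b.value[:, None]).reshape((w.value.shape[0],) + spatial)

    def bwd(g):
        gf = g.reshape(g.shape[0], -1)
        dx = (w.value.T @ gf).reshape(x.value.shape)
        dw = gf @ xf.T
        db = gf.sum(axis=1)
        return (dx, dw, db)

    return Var(val, (x, w, b), bwd, name="linear")


def resize_linear_nd(x: Var, out_dims: tuple[int, int, int]) -> Var:
    """Trilinear resize of a (C, D, H, W) field; parameter-free linear map."""
    spatial = x.value.shape[1:]
    mats = [
        linear_axis_matrix(n, m).astype(x.value.dtype)
        for n, m in zip(spatial, out_dims)
    ]

    def apply(data, matrices):
        out = data
        for ax, a in enumerate(matrices):
            out = np.moveaxis(np.tensordot(a, out, axes=(1, ax + 1)), 0, ax + 1)
        return out

    val = apply(x.value, mats)

    def bwd(g):
        return (apply(g, [a.T for a in mats]),)

    return Var(val, (x,), bwd, name="upscale")


def mean_abs_error(pred: Var, target: np.ndarray) -> Var:
    """Mean absolute voxel difference (data-consistency term)."""
    target = np.asarray(target)
    if pred.value.shape != target.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.value.shape} vs target {target.shape}"
        )
    diff = pred.value - target
    val = np.abs(diff).mean()

    def bwd(g):
        return (g * np.sign(diff) / diff.size,)

    return Var(np.asarray(val), (pred,), bwd, name="l1")


def masked_spectral_l1(
    pred: Var, target_spec: np.ndarray, mask: np.ndarray, reduction: str = "mean"
) -> Var:
    """L1 norm of the masked orthonormal-spectrum difference.

    ``target_spec`` is the precomputed orthonormal FFT of the reference
    volume in the unshifted (dc-at-corner) layout; ``mask`` matches that
    layout.  For ``L = sum_k |M_k (F[u]_k - G_k)| / denom`` the gradient
    with respect to the real field ``u`` is
    ``Re(FFT[M * conj(Z) / |Z|]) / denom`` with ``Z`` the masked
    difference (the forward transform appears because the orthonormal DFT
    matrix is symmetric).
    """
    if pred.value.shape != target_spec.shape:
        raise ValueError("prediction and reference spectrum shapes differ")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    z = mask * (np.fft.fftn(pred.value, norm="ortho") - target_spec)
    absz = np.abs(z)
    denom = float(mask.sum()) if reduction == "mean" else 1.0
    denom = max(denom, 1.0)
    val = absz.sum() / denom

    def bwd(g):
        with np.errstate(invalid="ignore", divide="ignore"):
            phase = np.where(absz > 0, np.conj(z) / np.where(absz > 0, absz, 1.0), 0.0)
        grad = np.real(np.fft.fftn(mask * phase, norm="ortho")) / denom
        return (g * grad.astype(pred.value.dtype),)

    return Var(np.asarray(val), (pred,), bwd, name="masked_spectral_l1")


def add_scaled(a: Var, b: Var, scale: float) -> Var:
    """Scalar combination ``a + scale * b`` (the composite loss)."""
    val = a.value + scale * b.value

    def bwd(g):
        return (g, g * scale)

    return Var(np.asarray(val), (a, b), bwd, name="add_scaled")
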
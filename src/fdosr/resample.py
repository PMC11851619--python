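"""Separable grid resampling used by degradation, the network's upscale
step, and the nearest-neighbor baseline.

One geometric mapping is used everywhere: output voxel center ``i`` on an
``M``-voxel axis maps to input coordinate ``(i + 0.5) * N / M - 0.5`` on an
``N``-voxel axis (cell-centered / "align corners false").  Linear
resampling is expressed as a per-axis matrix product, which makes the
adjoint (needed for backpropagation through the upscale layer) a plain
transpose, and makes the interpolation weights an explicit partition of
unity so constant fields are preserved.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "linear_axis_matrix",
    "nearest_axis_matrix",
    "resize_linear",
    "resize_nearest",
    "apply_axis_matrices",
]


def _source_coords(n_in: int, n_out: int) -> np.ndarray:
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    return np.clip(src, 0.0, n_in - 1.0)


def linear_axis_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) linear-interpolation matrix; rows sum to 1."""
    if n_in == 1:
        return np.ones((n_out, 1))
    src = _source_coords(n_in, n_out)
    i0 = np.minimum(np.floor(src).astype(np.intp), n_in - 2)
    t = src - i0
    rows = np.arange(n_out)
    a = np.zeros((n_out, n_in))
    a[rows, i0] = 1.0 - t
    a[rows, i0 + 1] += t
    return a


def nearest_axis_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) nearest-neighbor selection matrix (copy-only rows)."""
    src = _source_coords(n_in, n_out)
    idx = np.clip(np.round(src).astype(np.intp), 0, n_in - 1)
    a = np.zeros((n_out, n_in))
    a[np.arange(n_out), idx] = 1.0
    return a


def apply_axis_matrices(data: np.ndarray, mats: tuple[np.ndarray, ...]) -> np.ndarray:
    """Apply one matrix per trailing spatial axis of ``data``.

    ``data`` may be 3D ``(D, H, W)`` or 4D channels-first ``(C, D, H, W)``.
    """
    nd = data.ndim
    if nd not in (3, 4):
        raise ValueError(f"expected 3D or 4D array, got ndim={nd}")
    out = data
    first = nd - 3
    for k, a in enumerate(mats):
        axis = first + k
        out = np.moveaxis(np.tensordot(a, out, axes=(1, axis)), 0, axis)
    return out


def resize_linear(data: np.ndarray, out_dims: tuple[int, int, int]) -> np.ndarray:
    spatial = data.shape[-3:]
    mats = tuple(linear_axis_matrix(n, m) for n, m in zip(spatial, out_dims))
    out = apply_axis_matrices(data.astype(np.float64, copy=False), mats)
    return out.astype(data.dtype, copy=False)


def resize_nearest(data: np.ndarray, out_dims: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbor resize via direct index lookup (values are copies)."""
    spatial = data.shape[-3:]
    idx = tuple(
        np.clip(np.round(_source_coords(n, m)).astype(np.intp), 0, n - 1)
        for n, m in zip(spatial, out_dims)
    )
    if data.ndim == 3:
        return data[np.ix_(*idx)]
    return data[(slice(None),) + np.ix_(*idx)]
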
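"""Grid-size rules shared by the degradation and super-resolution paths.

All shape arithmetic in the package goes through these two functions so the
downsampling and upsampling sides stay mutually consistent:

* degrading an ``N``-voxel axis by factor ``s`` yields ``floor(N / s)``
  voxels (never extrapolates beyond the field of view);
* super-resolving an ``M``-voxel axis by factor ``s`` yields
  ``round(M * s)`` voxels (round half up).

For non-integer factors the composition ``round(floor(N/s) * s)`` can fall
short of ``N`` by up to ``ceil(s) - 1`` voxels; during training the target
grid is therefore always taken from the stored high-resolution volume.
"""
from __future__ import annotations

import math

__all__ = ["downsampled_dims", "upsampled_dims"]


def downsampled_dims(dims: tuple[int, ...], s: float) -> tuple[int, ...]:
    """Output grid dimensions of degrading ``dims`` by factor ``s``: floor(N/s)."""
    if s < 1:
        raise ValueError(f"scale factor must be >= 1, got {s}")
    return tuple(int(math.floor(n / s)) for n in dims)


def upsampled_dims(dims: tuple[int, ...], s: float) -> tuple[int, ...]:
    """Output grid dimensions of super-resolving ``dims`` by ``s``: round(N*s)."""
    if s < 1:
        raise ValueError(f"scale factor must be >= 1, got {s}")
    return tuple(int(math.floor(n * s + 0.5)) for n in dims)
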
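"""Core in-memory container for real-valued 3D intensity volumes.

A :class:`Volume3D` holds a real 3D grid of intensities together with its
voxel spacing (mm/voxel).  Intensities are expected to be normalized to
[0, 1] (via :meth:`Volume3D.normalize`) before any training or metric
computation, which makes PSNR with ``data_range=1`` well defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume3D", "ScaleFactor"]


@dataclass
class Volume3D:
    """Real-valued 3D intensity grid with voxel spacing.

    Parameters
    ----------
    data
        3D array of finite real intensities.
    spacing
        Voxel spacing per axis in mm/voxel (positive).
    affine
        Optional 4x4 voxel-to-world matrix carried through file round-trips.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D expects a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D intensities must all be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be a positive triple, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def normalize(self) -> "Volume3D":
        """Min-max normalize intensities to [0, 1].

        A spatially constant volume maps to all zeros (the range is
        degenerate, so any constant in [0, 1] would do).
        """
        lo = float(self.data.min())
        hi = float(self.data.max())
        if hi > lo:
            out = (self.data - lo) / (hi - lo)
        else:
            out = np.zeros_like(self.data)
        return replace(self, data=out)

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class ScaleFactor:
    """A super-resolution factor: ratio of high- to low-resolution grid size.

    Training draws are restricted to [2, 4]; any real value >= 1 is valid
    at inference time.
    """

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 1:
            raise ValueError(f"scale factor must be a finite real >= 1, got {self.value}")

    def __float__(self) -> float:
        return float(self.value)


def as_factor(s: "ScaleFactor | float") -> float:
    """Coerce a ScaleFactor or plain number to a validated float."""
    return float(ScaleFactor(float(s)))
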
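"""Volume and corpus I/O.

Volumes travel as NIfTI-1 (optionally gzipped) with voxel spacing in the
header; phantom corpora are also persisted as a single HDF5 container,
which is much faster for test fixtures and pipelines than many small
files.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .volume import Volume3D

__all__ = [
    "VolumeIOError",
    "NonFiniteVolumeError",
    "read_volume",
    "write_volume",
    "save_corpus",
    "load_corpus",
]


class VolumeIOError(RuntimeError):
    """A volume file is missing, unparseable, or unwritable."""


class NonFiniteVolumeError(VolumeIOError):
    """A volume file contains NaN or infinite voxels."""


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI volume; rejects non-finite data with a named error."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # corrupt / unparseable
        raise VolumeIOError(f"could not parse volume file {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeIOError(f"{path} holds a {data.ndim}D array; expected 3D")
    if not np.all(np.isfinite(data)):
        raise NonFiniteVolumeError(f"{path} contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1; intensities are written unmodified."""
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"could not write volume to {path}: {exc}") from exc


def save_corpus(path, corpus: list[tuple[str, str, Volume3D]]) -> None:
    """Persist (volume_id, contrast_profile, volume) triples to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for vol_id, profile, vol in corpus:
            ds = f.create_dataset(vol_id, data=vol.data)
            ds.attrs["contrast_profile"] = profile
            ds.attrs["spacing"] = vol.spacing


def load_corpus(path) -> list[tuple[str, str, Volume3D]]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"corpus file not found: {path}")
    out = []
    with h5py.File(path, "r") as f:
        for vol_id in sorted(f.keys()):
            ds = f[vol_id]
            vol = Volume3D(ds[()], spacing=tuple(ds.attrs["spacing"]))
            out.append((vol_id, str(ds.attrs["contrast_profile"]), vol))
    return out
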
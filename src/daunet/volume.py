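"""Volume/Mask containers and NIfTI I/O.

Arrays are indexed ``(z, y, x)``, 0-based, with per-axis voxel spacing in
millimetres stored alongside.  On disk the data are transposed to the
NIfTI-conventional ``(x, y, z)`` order with the spacing carried in the
affine, so files interoperate with external viewers; a write/read round
trip is bit-exact for the data and float-exact for the spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "Mask", "read_volume", "write_volume", "read_mask", "write_mask"]


def _default_affine(spacing_mm):
    sz, sy, sx = spacing_mm
    return np.diag([sx, sy, sz, 1.0])


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing (z, y, x) in mm."""

    data: np.ndarray
    spacing_mm: tuple
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got {self.data.ndim}-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data, spacing_mm=None):
        return type(self)(
            np.asarray(data),
            self.spacing_mm if spacing_mm is None else spacing_mm,
            self.affine.copy(),
        )


@dataclass
class Mask(Volume):
    """A binary label grid aligned to a Volume; values in {0, 1}."""

    def __post_init__(self):
        super().__post_init__()
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be exactly {0, 1}")
        self.data = arr.astype(np.uint8)


def _read(path):
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D NIfTI image, got {arr.ndim}-D")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return data, spacing, np.asarray(img.affine)


def read_volume(path) -> Volume:
    data, spacing, affine = _read(path)
    return Volume(data, spacing, affine)


def read_mask(path) -> Mask:
    data, spacing, affine = _read(path)
    return Mask(np.rint(data).astype(np.uint8), spacing, affine)


def write_volume(vol: Volume, path) -> None:
    data = np.ascontiguousarray(vol.data.transpose(2, 1, 0))
    img = nib.Nifti1Image(data, vol.affine)
    sz, sy, sx = vol.spacing_mm
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


write_mask = write_volume
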
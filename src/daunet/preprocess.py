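"""CT preprocessing pipeline for volumetric liver segmentation.

Fixed stage order (images and masks move through jointly):

    clip_hu -> resample_z -> crop_liver_span -> in-plane resize
            -> normalize01 -> extract_patches

Intensities are clamped to the [-200, 200] HU soft-tissue window, the z
axis is resampled to 1 mm, the z-extent is cropped to the organ span
expanded by 20 slices, the in-plane grid is resized to 256x256, and
intensities are rescaled to [0, 1].  Images are interpolated linearly,
masks with nearest neighbour (so they stay binary); every geometric
stage updates the recorded voxel spacing so downstream surface metrics
work in true millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import linear_resize_matrix, nearest_resize_indices, _apply_axis
from .volume import Mask, Volume

__all__ = [
    "PreprocessConfig",
    "SpanRecord",
    "clip_hu",
    "normalize01",
    "resample_z",
    "crop_liver_span",
    "uncrop_z",
    "resize_inplane",
    "resize_to_shape",
    "extract_patches",
    "reassemble",
    "preprocess_pair",
]


@dataclass
class PreprocessConfig:
    hu_lo: float = -200.0
    hu_hi: float = 200.0
    inplane_size: int = 256
    z_spacing_mm: float = 1.0
    span_margin_slices: int = 20
    patch_depth: int = 16
    stride_z: int = 16

    def __post_init__(self):
        if self.hu_lo >= self.hu_hi:
            raise ValueError("hu_lo must be < hu_hi")
        if self.span_margin_slices < 0:
            raise ValueError("margin must be >= 0")
        if self.z_spacing_mm <= 0:
            raise ValueError("z spacing must be positive")
        if not (1 <= self.stride_z <= self.patch_depth):
            raise ValueError("stride_z must be in [1, patch_depth]")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown PreprocessConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SpanRecord:
    """Original z-placement of a crop, for restoring predictions."""

    z_start: int
    z_stop: int  # inclusive
    original_depth: int


def clip_hu(vol: Volume, lo: float = -200.0, hi: float = 200.0) -> Volume:
    if lo >= hi:
        raise ValueError(f"invalid HU window ({lo}, {hi})")
    return vol.with_data(np.clip(vol.data, lo, hi))


def normalize01(vol: Volume) -> Volume:
    data = np.asarray(vol.data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant volume")
    return vol.with_data((data - lo) / (hi - lo))


def _resize_axis(data: np.ndarray, axis: int, n_out: int, order: int) -> np.ndarray:
    n_in = data.shape[axis]
    if n_in == n_out:
        return data
    if order == 0:
        idx = nearest_resize_indices(n_in, n_out)
        return np.take(data, idx, axis=axis)
    M = linear_resize_matrix(n_in, n_out)
    return _apply_axis(np.asarray(data, dtype=np.float32), M.astype(np.float32), axis)


def resample_z(vol: Volume, target_mm: float = 1.0, order: int = 1) -> Volume:
    """Resample the z axis to ``target_mm`` spacing (linear for images,
    ``order=0`` nearest for masks); in-plane axes untouched."""
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    old = vol.spacing_mm[0]
    depth = vol.shape[0]
    new_depth = int(round(depth * old / target_mm))
    if new_depth < 1:
        raise ValueError(
            f"target spacing {target_mm} mm coarser than the volume extent "
            f"({depth} slices at {old} mm)"
        )
    data = _resize_axis(vol.data, 0, new_depth, order)
    if isinstance(vol, Mask):
        data = data.astype(np.uint8)
    return vol.with_data(data, (target_mm,) + vol.spacing_mm[1:])


def crop_liver_span(vol: Volume, mask: Mask, margin: int = 20):
    """Crop both grids to [first organ slice - margin, last + margin]."""
    fg = np.flatnonzero(mask.data.reshape(mask.shape[0], -1).any(axis=1))
    if fg.size == 0:
        raise ValueError("cannot locate the organ span: mask is empty")
    depth = vol.shape[0]
    z0 = max(0, int(fg[0]) - margin)
    z1 = min(depth - 1, int(fg[-1]) + margin)
    rec = SpanRecord(z0, z1, depth)
    return (
        vol.with_data(vol.data[z0:z1 + 1]),
        mask.with_data(mask.data[z0:z1 + 1]),
        rec,
    )


def uncrop_z(vol: Volume, rec: SpanRecord, fill=0) -> Volume:
    """Place a cropped prediction back at its original z position."""
    out = np.full((rec.original_depth,) + vol.shape[1:], fill, dtype=vol.data.dtype)
    out[rec.z_start:rec.z_stop + 1] = vol.data
    return vol.with_data(out)


def resize_inplane(vol: Volume, size: int, order: int = 1) -> Volume:
    """Resize the (y, x) axes to ``size`` x ``size``."""
    data = vol.data
    ny, nx = data.shape[1], data.shape[2]
    data = _resize_axis(data, 1, size, order)
    data = _resize_axis(data, 2, size, order)
    if isinstance(vol, Mask):
        data = data.astype(np.uint8)
    sz, sy, sx = vol.spacing_mm
    return vol.with_data(data, (sz, sy * ny / size, sx * nx / size))


def resize_to_shape(vol: Volume, shape, order: int = 1) -> Volume:
    """Resize all three axes to ``shape`` (trilinear / nearest)."""
    data = vol.data
    for ax in range(3):
        data = _resize_axis(data, ax, shape[ax], order)
    if isinstance(vol, Mask):
        data = data.astype(np.uint8)
    spacing = tuple(
        s * n_in / n_out for s, n_in, n_out in zip(vol.spacing_mm, vol.shape, shape)
    )
    return vol.with_data(data, spacing)


def extract_patches(data: np.ndarray, patch_depth: int = 16, stride_z: int = 16):
    """Tile a (Z, Y, X) array along z into full-depth patches.

    Patches start at 0, stride_z, ... with the last patch right-aligned
    (overlap allowed).  Volumes shallower than ``patch_depth`` are
    zero-padded at the bottom; the pad amount is recorded for stripping
    at reassembly.  Returns (patches, placements, pad).
    """
    data = np.asarray(data)
    depth = data.shape[0]
    pad = max(0, patch_depth - depth)
    if pad:
        data = np.concatenate(
            [data, np.zeros((pad,) + data.shape[1:], dtype=data.dtype)], axis=0
        )
        depth = patch_depth
    offsets = list(range(0, depth - patch_depth + 1, stride_z))
    if offsets[-1] != depth - patch_depth:
        offsets.append(depth - patch_depth)
    patches = [data[o:o + patch_depth] for o in offsets]
    return patches, offsets, pad


def reassemble(patches, placements, out_depth: int, pad: int = 0) -> np.ndarray:
    """Average overlapping z-tiles back into a (out_depth, Y, X) array."""
    patches = [np.asarray(p, dtype=np.float32) for p in patches]
    pd = patches[0].shape[0]
    padded = out_depth + pad
    acc = np.zeros((padded,) + patches[0].shape[1:], dtype=np.float32)
    cnt = np.zeros(padded, dtype=np.float32)
    for p, o in zip(patches, placements):
        acc[o:o + pd] += p
        cnt[o:o + pd] += 1.0
    if (cnt == 0).any():
        raise ValueError("placements do not cover the full z extent")
    acc /= cnt[:, None, None]
    return acc[:out_depth]


def preprocess_pair(vol: Volume, mask: Mask | None, cfg: PreprocessConfig,
                    crop: bool = True):
    """Run the full pipeline; returns (vol, mask, span_record or None).

    ``mask=None`` (inference without a ground truth) skips the span crop;
    masks travel through every geometric stage with nearest-neighbour
    interpolation.
    """
    vol = clip_hu(vol, cfg.hu_lo, cfg.hu_hi)
    vol = resample_z(vol, cfg.z_spacing_mm, order=1)
    if mask is not None:
        mask = resample_z(mask, cfg.z_spacing_mm, order=0)
    rec = None
    if crop and mask is not None:
        vol, mask, rec = crop_liver_span(vol, mask, cfg.span_margin_slices)
    vol = resize_inplane(vol, cfg.inplane_size, order=1)
    if mask is not None:
        mask = resize_inplane(mask, cfg.inplane_size, order=0)
    vol = normalize01(vol)
    return vol, mask, rec
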
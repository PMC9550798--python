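"""Seeded synthetic CT phantoms with exact ground-truth masks.

Each phantom emulates the situations that make liver CT segmentation
hard: a bright quasi-ellipsoidal organ (~100 HU soft tissue) composed of
a primary ellipsoid plus a few jittered child lobes (so the boundary is
non-convex), an adjacent organ of nearly identical intensity (the
low-contrast worst case), an optional lesion straddling the boundary
(labelled as organ), and tubular vessels of background-like intensity
inside the organ (intensity holes that remain organ in the ground
truth).  Gaussian per-voxel texture and additive acquisition noise are
applied on top, and voxel spacing may be anisotropic.

Intensities are generated in Hounsfield units so the standard
[-200, 200] preprocessing window is meaningful.  Output is a pure,
bit-reproducible function of the spec (including its seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .volume import Mask, Volume, write_mask, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "make_dataset", "read_manifest"]


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 96, 96)
    spacing_mm: tuple = (2.0, 1.5, 1.5)
    organ_center: tuple = None  # defaults to the grid centre
    organ_radii: tuple = (22.0, 30.0, 30.0)
    n_lobes: int = 2
    organ_hu_mean: float = 100.0
    organ_hu_sd: float = 8.0
    background_hu_mean: float = 20.0
    background_hu_sd: float = 8.0
    neighbor_offset: tuple = None  # e.g. (0, 0, 60); None disables the neighbor
    neighbor_radii: tuple = (14.0, 18.0, 18.0)
    neighbor_hu_mean: float = 95.0
    lesion_on_boundary: bool = False
    lesion_radius_vox: float = 4.0
    lesion_hu: float = 60.0
    vessel_count: int = 0
    vessel_radius_vox: float = 1.5
    vessel_hu: float = 40.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.organ_center is None:
            self.organ_center = tuple((s - 1) / 2.0 for s in self.grid_shape)
        self.organ_center = tuple(float(c) for c in self.organ_center)
        self.organ_radii = tuple(float(r) for r in self.organ_radii)
        if any(r <= 0 for r in self.organ_radii):
            raise ValueError("organ radii must be positive")
        if self.neighbor_offset is not None and any(r <= 0 for r in self.neighbor_radii):
            raise ValueError("neighbor radii must be positive")
        if self.lesion_on_boundary and self.lesion_radius_vox <= 0:
            raise ValueError("lesion radius must be positive")
        if self.vessel_count and self.vessel_radius_vox <= 0:
            raise ValueError("vessel radius must be positive")
        if self.noise_sd < 0 or self.organ_hu_sd < 0 or self.background_hu_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not (0 <= self.n_lobes <= 3):
            raise ValueError("n_lobes must be in 0..3")
        # the primary organ ellipsoid (and its child lobes, whose extent is
        # bounded by 0.85 * organ_radii) must fit inside the grid
        for c, r, s in zip(self.organ_center, self.organ_radii, self.grid_shape):
            if c - r < -0.5 or c + r > s - 0.5:
                raise ValueError(
                    f"organ ellipsoid (centre {self.organ_center}, radii "
                    f"{self.organ_radii}) does not fit inside grid {self.grid_shape}"
                )

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PhantomSpec keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def _ellipsoid(grid_shape, center, radii):
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij")
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _organ_mask(spec: PhantomSpec, rng: np.random.Generator):
    organ = _ellipsoid(spec.grid_shape, spec.organ_center, spec.organ_radii)
    r = np.asarray(spec.organ_radii)
    for _ in range(spec.n_lobes):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        centre = np.asarray(spec.organ_center) + u * r * 0.4
        organ |= _ellipsoid(spec.grid_shape, centre, r * 0.45)
    return organ


def generate_phantom(spec: PhantomSpec):
    """Render one phantom; returns ``(Volume, Mask)``.

    The mask is 1 exactly on the organ union (primary ellipsoid, lobes,
    and the boundary lesion if enabled); vessels and the neighbor organ
    never add mask voxels.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape

    organ = _organ_mask(spec, rng)
    mask = organ.copy()

    hu = np.full(shape, spec.background_hu_mean, dtype=np.float64)
    if spec.background_hu_sd > 0:
        hu += rng.normal(0.0, spec.background_hu_sd, shape)

    texture = rng.normal(0.0, 1.0, shape)  # shared texture field, scaled per structure

    if spec.neighbor_offset is not None:
        centre = np.asarray(spec.organ_center) + np.asarray(spec.neighbor_offset, dtype=float)
        neighbor = _ellipsoid(shape, centre, spec.neighbor_radii) & ~organ
        hu[neighbor] = spec.neighbor_hu_mean + spec.organ_hu_sd * texture[neighbor]

    hu[organ] = spec.organ_hu_mean + spec.organ_hu_sd * texture[organ]

    # vessels: background-like tubes inside the organ, still labelled organ
    for _ in range(spec.vessel_count):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        offset = rng.uniform(-0.3, 0.3, 3) * np.asarray(spec.organ_radii)
        point = np.asarray(spec.organ_center) + offset
        zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        rel = np.stack([zz - point[0], yy - point[1], xx - point[2]], axis=-1)
        along = rel @ axis
        radial2 = (rel * rel).sum(-1) - along ** 2
        tube = (radial2 <= spec.vessel_radius_vox ** 2) & organ
        hu[tube] = spec.vessel_hu

    if spec.lesion_on_boundary:
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        centre = np.asarray(spec.organ_center) + u * np.asarray(spec.organ_radii)
        centre = np.clip(centre, 0, np.asarray(shape) - 1)
        lesion = _ellipsoid(shape, centre, (spec.lesion_radius_vox,) * 3)
        hu[lesion] = spec.lesion_hu
        mask |= lesion

    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, shape)

    vol = Volume(hu.astype(np.float32), spec.spacing_mm)
    return vol, Mask(mask.astype(np.uint8), spec.spacing_mm)


def _case_seeds(seed: int, n: int):
    # derived deterministically; kept below 2**31 for portability
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31) for s in state]


def make_dataset(spec: PhantomSpec, n_cases: int, out_dir, variation=None):
    """Write ``n_cases`` image/mask NIfTI pairs plus a manifest TSV.

    ``variation`` maps PhantomSpec field names to (lo, hi) jitter ranges
    sampled uniformly per case (scalars only).  Per-case seeds are derived
    deterministically from ``spec.seed``; two runs with the same spec
    produce identical files.  Returns the manifest path.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _case_seeds(spec.seed, n_cases)
    rows = []
    for i, case_seed in enumerate(seeds):
        case_spec = replace(spec, seed=case_seed)
        if variation:
            jrng = np.random.default_rng(case_seed)
            overrides = {}
            for name, (lo, hi) in sorted(variation.items()):
                base = getattr(case_spec, name)
                if isinstance(base, tuple):
                    overrides[name] = tuple(b + jrng.uniform(lo, hi) for b in base)
                else:
                    overrides[name] = type(base)(base + jrng.uniform(lo, hi))
            case_spec = replace(case_spec, **overrides)
        vol, mask = generate_phantom(case_spec)
        img_path = out_dir / f"case_{i:03d}_image.nii.gz"
        msk_path = out_dir / f"case_{i:03d}_mask.nii.gz"
        write_volume(vol, img_path)
        write_mask(mask, msk_path)
        rows.append((str(img_path), str(msk_path), case_seed))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("image\tmask\tseed\n")
        for img, msk, s in rows:
            fh.write(f"{img}\t{msk}\t{s}\n")
    return manifest


def read_manifest(path):
    """Parse a manifest TSV into a list of (image, mask, seed) tuples."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["image", "mask", "seed"]:
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for line in fh:
            img, msk, seed = line.rstrip("\n").split("\t")
            rows.append((img, msk, int(seed)))
    return rows
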
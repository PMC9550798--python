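"""Volume- and surface-based segmentation metrics.

Five metrics are reported per case, with A the predicted mask and B the
ground truth:

* Dice      2|A∩B| / (|A| + |B|)
* VOE       1 - |A∩B| / |A∪B|            (volume overlap error)
* RVD       (|B| - |A|) / |A|            (signed relative volume difference)
* ASD       mean of all directed nearest-surface distances, pooled over
            S(A)->S(B) and S(B)->S(A), in mm
* RMSD      root of the mean of the squared pooled distances, in mm

Surfaces are the foreground voxels with at least one 6-neighbour outside
the mask (volume-border foreground counts as surface).  Distances are
Euclidean between voxel centres with anisotropic spacing folded in via a
spacing-weighted exact distance transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "dice",
    "voe",
    "rvd",
    "surface_voxels",
    "asd",
    "rmsd",
    "surface_distances",
    "evaluate_case",
]


@dataclass
class MetricsReport:
    dice: float
    voe: float
    rvd: float
    asd_mm: float
    rmsd_mm: float
    n_surface_a: int
    n_surface_b: int
    spacing_mm: tuple

    def row(self):
        return (self.dice, self.voe, self.rvd, self.asd_mm, self.rmsd_mm)


def _as_bool(m):
    arr = np.asarray(getattr(m, "data", m))
    return arr.astype(bool)


def dice(a, b) -> float:
    A, B = _as_bool(a), _as_bool(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na == 0 and nb == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def voe(a, b) -> float:
    A, B = _as_bool(a), _as_bool(b)
    union = int((A | B).sum())
    if union == 0:
        warnings.warn("both masks empty; VOE defined as 0.0", stacklevel=2)
        return 0.0
    return 1.0 - int((A & B).sum()) / union


def rvd(a, b) -> float:
    A, B = _as_bool(a), _as_bool(b)
    na = int(A.sum())
    if na == 0:
        raise ValueError("RVD undefined: segmentation A is empty")
    return (int(B.sum()) - na) / na


def surface_voxels(m, connectivity: int = 1) -> np.ndarray:
    """Boolean grid of surface voxels: foreground with a neighbour outside
    the mask.  ``connectivity`` 1 = faces (6 neighbours, the default),
    3 = faces+edges+corners (26).  Border foreground counts as surface."""
    M = _as_bool(m)
    struct = ndimage.generate_binary_structure(3, connectivity)
    interior = ndimage.binary_erosion(M, structure=struct, border_value=0)
    return M & ~interior


def surface_distances(a, b, spacing, connectivity: int = 1):
    """Pooled directed nearest-surface distances, in mm.

    Returns the concatenation of d(p, S(B)) for p in S(A) and d(q, S(A))
    for q in S(B); exact Euclidean via the spacing-weighted distance
    transform.
    """
    A, B = _as_bool(a), _as_bool(b)
    if not A.any() or not B.any():
        raise ValueError("surface distances undefined for an empty mask")
    sa, sb = surface_voxels(A, connectivity), surface_voxels(B, connectivity)
    spacing = tuple(float(s) for s in spacing)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return np.concatenate([dt_b[sa], dt_a[sb]])


def asd(a, b, spacing) -> float:
    return float(surface_distances(a, b, spacing).mean())


def rmsd(a, b, spacing) -> float:
    d = surface_distances(a, b, spacing)
    return float(np.sqrt((d * d).mean()))


def evaluate_case(a, b, spacing) -> MetricsReport:
    """All five metrics for one predicted/truth mask pair."""
    d = surface_distances(a, b, spacing)
    return MetricsReport(
        dice=dice(a, b),
        voe=voe(a, b),
        rvd=rvd(a, b),
        asd_mm=float(d.mean()),
        rmsd_mm=float(np.sqrt((d * d).mean())),
        n_surface_a=int(surface_voxels(a).sum()),
        n_surface_b=int(surface_voxels(b).sum()),
        spacing_mm=tuple(float(s) for s in spacing),
    )
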
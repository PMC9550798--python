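"""Fully connected CRF refinement of network probability maps.

The refinement minimizes (approximately, by mean-field iteration) a
dense-CRF energy with unary terms from the network probabilities and two
Gaussian pairwise kernels under a Potts compatibility:

    k(i,j) = w_app    * exp(-|pi-pj|^2 / 2*th_pos_app^2
                            - (Ii-Ij)^2 / 2*th_int^2)        (appearance)
           + w_smooth * exp(-|pi-pj|^2 / 2*th_pos_smooth^2)  (smoothness)

The appearance kernel couples voxels that are both near and similar in
intensity — it snaps labels to intensity edges; the smoothness kernel
removes isolated misclassified voxels.  The mean-field update is

    Q'_i(l) ∝ exp( -u_i(l) - sum_{j != i} k(i,j) * (1 - Q_j(l)) )

i.e. a softmax of the negated unary plus Potts messages.

Two evaluation modes are provided.  ``exact`` materializes the full
N x N kernel (capped at 20 000 voxels) and is the reference used by the
tests.  ``approximate`` evaluates the smoothness message with separable
truncated-Gaussian convolutions and the appearance message with a 4-D
bilateral grid (splat / blur / slice), which scales to full volumes.

Positions are measured in voxel units by default; ``use_mm_positions``
folds the voxel spacing in for anisotropic volumes.  At exactly tied
label scores the background label (0) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .volume import Mask, Volume

__all__ = ["CRFParams", "DenseCRF", "mean_field_step", "refine"]

EXACT_VOXEL_CAP = 20_000


@dataclass
class CRFParams:
    w_app: float = 1.0
    w_smooth: float = 1.0
    theta_pos_app: float = 10.0
    theta_int: float = 0.1
    theta_pos_smooth: float = 3.0
    n_iters: int = 5
    mode: str = "exact"  # {"exact", "approximate"}
    use_mm_positions: bool = False

    def __post_init__(self):
        if min(self.theta_pos_app, self.theta_int, self.theta_pos_smooth) <= 0:
            raise ValueError("kernel bandwidths must be > 0")
        if self.w_app < 0 or self.w_smooth < 0:
            raise ValueError("kernel weights must be >= 0")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.mode not in ("exact", "approximate"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown CRFParams keys: {sorted(unknown)}")
        return cls(**d)


def _softmax_neg(scores):
    """Row-wise softmax of -scores, numerically stabilized."""
    z = -scores
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _gauss_weights(sigma):
    radius = max(1, int(np.ceil(4.0 * sigma)))
    k = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-(k * k) / (2.0 * sigma * sigma))


def _separable_gauss(field, sigmas):
    """Unnormalized separable Gaussian filtering (kernel value 1 at 0)."""
    out = np.asarray(field, dtype=np.float64)
    for ax, s in enumerate(sigmas):
        out = ndimage.correlate1d(out, _gauss_weights(s), axis=ax, mode="constant")
    return out


@lru_cache(maxsize=4)
def _spatial_kernels(shape, axis_scale, theta_app, theta_smooth):
    """Pairwise spatial Gaussian factors, cached: they depend only on the
    grid geometry, not on the image, so repeated refinement of same-shape
    ROIs rebuilds only the intensity factor."""
    coords = np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape], indexing="ij")
    pos = np.stack([c.ravel() * sc for c, sc in zip(coords, axis_scale)], axis=1)
    d2 = np.zeros((pos.shape[0], pos.shape[0]), dtype=np.float32)
    for ax in range(3):
        d2 += (pos[:, ax, None] - pos[None, :, ax]) ** 2
    return (
        np.exp(-d2 / (2 * theta_app ** 2)),
        np.exp(-d2 / (2 * theta_smooth ** 2)),
    )


class _BilateralGrid:
    """4-D (z, y, x, intensity) splat/blur/slice operator.

    Coordinates are pre-scaled by the kernel bandwidths, so the blur is
    an isotropic unit Gaussian in scaled space sampled every ``delta``
    units.
    """

    def __init__(self, scaled_coords, delta=0.5):
        self.delta = float(delta)
        pts = np.stack([c.ravel() / self.delta for c in scaled_coords], axis=1)
        self.lo = np.floor(pts.min(axis=0)).astype(int) - 1
        pts -= self.lo
        self.shape = tuple(int(np.ceil(pts[:, d].max())) + 2 for d in range(4))
        self.base = np.floor(pts).astype(int)
        self.frac = pts - self.base
        self.n = pts.shape[0]

    def _corners(self):
        for m in range(16):
            bits = [(m >> d) & 1 for d in range(4)]
            w = np.ones(self.n)
            idx = []
            for d, bit in enumerate(bits):
                w = w * (self.frac[:, d] if bit else 1.0 - self.frac[:, d])
                idx.append(self.base[:, d] + bit)
            yield tuple(idx), w

    def apply(self, values):
        """Approximate v -> sum_j exp(-|c_i-c_j|^2/2) v_j (self included)."""
        grid = np.zeros(self.shape)
        for idx, w in self._corners():
            np.add.at(grid, idx, w * values)
        sigma = 1.0 / self.delta
        for ax in range(4):
            grid = ndimage.correlate1d(grid, _gauss_weights(sigma), axis=ax, mode="constant")
        out = np.zeros(self.n)
        for idx, w in self._corners():
            out += w * grid[idx]
        return out


class DenseCRF:
    """Mean-field inference context for one (intensity, spacing) volume."""

    def __init__(self, intensity: np.ndarray, spacing, params: CRFParams):
        self.params = params
        self.intensity = np.asarray(intensity, dtype=np.float64)
        self.shape = self.intensity.shape
        self.n = self.intensity.size
        self.spacing = tuple(float(s) for s in spacing)
        scale = self.spacing if params.use_mm_positions else (1.0, 1.0, 1.0)
        self._axis_scale = scale
        if params.mode == "exact":
            if self.n > EXACT_VOXEL_CAP:
                raise ValueError(
                    f"exact mode refuses {self.n} voxels (cap {EXACT_VOXEL_CAP}); "
                    "use mode='approximate'"
                )
            self._kernel = self._build_kernel()
        else:
            coords = np.meshgrid(
                *[np.arange(s, dtype=float) for s in self.shape], indexing="ij"
            )
            scaled = [c * sc / params.theta_pos_app for c, sc in zip(coords, scale)]
            scaled.append(self.intensity / params.theta_int)
            self._grid = _BilateralGrid(scaled) if params.w_app > 0 else None

    def _build_kernel(self):
        p = self.params
        app, smooth = _spatial_kernels(
            self.shape, self._axis_scale, p.theta_pos_app, p.theta_pos_smooth
        )
        I = self.intensity.ravel().astype(np.float32)
        di2 = (I[:, None] - I[None, :]) ** 2
        K = p.w_app * app * np.exp(-di2 / (2 * p.theta_int ** 2)) + p.w_smooth * smooth
        np.fill_diagonal(K, 0.0)
        return K.astype(np.float64)

    def kernel_apply(self, v: np.ndarray) -> np.ndarray:
        """Evaluate sum_{j != i} k(i, j) v_j for a flat field v."""
        p = self.params
        if p.mode == "exact":
            return self._kernel @ v
        field = v.reshape(self.shape)
        out = np.zeros(self.n)
        if p.w_smooth > 0:
            sig = [p.theta_pos_smooth / sc for sc in self._axis_scale]
            out += p.w_smooth * (_separable_gauss(field, sig).ravel() - v)
        if p.w_app > 0 and self._grid is not None:
            out += p.w_app * (self._grid.apply(v) - v)
        return out

    def step(self, Q: np.ndarray, unary: np.ndarray) -> np.ndarray:
        """One mean-field update; Q and unary are (N, L), rows of Q normalized."""
        if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must be normalized")
        # Potts message: sum_j k(ij) * (1 - Q_j(l)); the label-independent
        # constant sum_j k(ij) cancels in the softmax, leaving the
        # attraction term -sum_j k(ij) Q_j(l).
        msg = np.empty_like(Q)
        for l in range(Q.shape[1]):
            msg[:, l] = self.kernel_apply(Q[:, l])
        return _softmax_neg(unary - msg)

    def run(self, unary: np.ndarray, n_iters: int | None = None) -> np.ndarray:
        n_iters = self.params.n_iters if n_iters is None else n_iters
        Q = _softmax_neg(unary)
        for _ in range(n_iters):
            Q = self.step(Q, unary)
        return Q


def mean_field_step(Q, unary, crf: DenseCRF):
    """Functional wrapper over :meth:`DenseCRF.step`."""
    return crf.step(np.asarray(Q, dtype=float), np.asarray(unary, dtype=float))


def unary_from_prob(prob: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Negative-log unary (N, 2) from a foreground-probability grid."""
    p = np.clip(np.asarray(prob, dtype=np.float64).ravel(), eps, 1.0 - eps)
    return -np.log(np.stack([1.0 - p, p], axis=1))


def flip_noise_benchmark(n_seeds: int = 100, seed0: int = 0,
                         params: CRFParams | None = None,
                         flip_rate: float = 0.05):
    """Synthetic refinement benchmark: does CRF repair flip-noise?

    For each seed a small phantom is rendered, its ground truth is turned
    into a confident probability map (0.95 inside, 0.05 outside) and a
    fraction ``flip_rate`` of voxels have their probability inverted.
    The benchmark counts the seeds where refinement strictly improves the
    Dice against ground truth over plain thresholding.  Returns
    ``(n_improved, mean_dice_gain)``.
    """
    from .metrics import dice as _dice
    from .phantom import PhantomSpec, generate_phantom
    from .preprocess import clip_hu, normalize01

    params = params or CRFParams(mode="exact")
    wins = 0
    gains = []
    for i in range(n_seeds):
        seed = seed0 + i
        rng = np.random.default_rng(seed)
        spec = PhantomSpec(
            grid_shape=(16, 16, 16), spacing_mm=(1.0, 1.0, 1.0),
            organ_center=(7.5, 7.5, 7.5), organ_radii=(5.0, 5.0, 5.0),
            n_lobes=1, neighbor_offset=None, noise_sd=10.0, seed=seed,
        )
        vol, mask = generate_phantom(spec)
        intensity = normalize01(clip_hu(vol))
        gt = mask.data.astype(float)
        prob = gt * 0.9 + 0.05
        flip = rng.random(gt.shape) < flip_rate
        prob = np.where(flip, 1.0 - prob, prob)
        raw = Mask((prob > 0.5).astype(np.uint8), vol.spacing_mm)
        refined = refine(Volume(prob, vol.spacing_mm), intensity, params)
        gain = _dice(refined, mask) - _dice(raw, mask)
        gains.append(gain)
        if gain > 0:
            wins += 1
    return wins, float(np.mean(gains))


def refine(prob: Volume, intensity: Volume, params: CRFParams = CRFParams()) -> Mask:
    """Refine a probability Volume against its intensity Volume.

    Returns the argmax labelling after ``params.n_iters`` mean-field
    iterations; ties go to background.
    """
    pdat = np.asarray(prob.data, dtype=np.float64)
    if prob.shape != intensity.shape:
        raise ValueError(f"grid mismatch: prob {prob.shape} vs intensity {intensity.shape}")
    if not np.allclose(prob.spacing_mm, intensity.spacing_mm):
        raise ValueError("spacing mismatch between probability and intensity volumes")
    if pdat.min() < -1e-9 or pdat.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    crf = DenseCRF(intensity.data, intensity.spacing_mm, params)
    Q = crf.run(unary_from_prob(pdat))
    labels = (Q[:, 1] > Q[:, 0]).astype(np.uint8)  # tie -> background
    return Mask(labels.reshape(prob.shape), prob.spacing_mm, prob.affine.copy())
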
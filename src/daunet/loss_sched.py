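"""Tversky loss, deep-supervision loss combination, and training schedules.

The Tversky index generalizes Dice by weighting false positives with
``alpha`` and false negatives with ``beta`` (alpha + beta = 1); pushing
``beta`` above 0.5 penalizes missed organ voxels more than spurious ones,
which counteracts the foreground/background imbalance of abdominal CT.
With ``alpha = beta = 0.5`` and linear penalty terms the loss reduces to
the Dice loss.

``squared_penalties=True`` (the default) squares the per-voxel FP and FN
terms inside the denominator sums; the conventional Tversky index uses
the linear terms and is available with ``squared_penalties=False``. For
binary predictions the two coincide (t^2 = t on {0,1}); the Dice
equivalence at alpha = beta = 0.5 on *soft* predictions holds only for
the linear form.

Deep supervision combines the main-head loss with three auxiliary-head
losses, L = L_main + ds_alpha * (L1 + L2 + L3), where the coefficient
decays by a factor 0.8 every 40 epochs. The learning rate starts at 1e-3
and is multiplied by gamma = 0.1 at epochs 350 and 650.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, constant, sum_all

__all__ = [
    "TverskyParams",
    "DSState",
    "tversky_loss",
    "dice_loss",
    "ds_loss",
    "update_ds_alpha",
    "lr_at_epoch",
]


@dataclass
class TverskyParams:
    alpha: float = 0.4
    beta: float = 0.6
    squared_penalties: bool = True
    smooth: float = 1e-6

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError(f"alpha + beta must equal 1, got {self.alpha + self.beta}")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")


@dataclass
class DSState:
    """Deep-supervision coefficient state; ds_alpha is a pure function of epoch."""

    ds_alpha0: float = 1.0
    decay_every: int = 40
    decay_factor: float = 0.8
    epoch: int = 0

    @property
    def ds_alpha(self) -> float:
        return self.ds_alpha0 * self.decay_factor ** (self.epoch // self.decay_every)


def update_ds_alpha(state: DSState, epoch: int) -> DSState:
    """Return the state advanced to ``epoch`` (stateless, idempotent)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return DSState(state.ds_alpha0, state.decay_every, state.decay_factor, epoch)


def lr_at_epoch(epoch: int, base: float = 0.001, milestones=(350, 650), gamma: float = 0.1) -> float:
    if list(milestones) != sorted(milestones):
        raise ValueError("milestones must be sorted ascending")
    return base * gamma ** sum(1 for m in milestones if m <= epoch)


def _prep(p, g):
    pt = p if isinstance(p, Tensor) else constant(np.asarray(p, dtype=float))
    gd = np.asarray(g.data if isinstance(g, Tensor) else g)
    if pt.shape == (1,) + gd.shape:  # singleton channel axis from an output head
        gd = gd[None]
    if pt.shape != gd.shape:
        raise ValueError(f"shape mismatch: prediction {pt.shape} vs target {gd.shape}")
    pd = np.asarray(pt.data)
    if pd.min() < -1e-6 or pd.max() > 1 + 1e-6:
        raise ValueError("predictions must lie in [0, 1]")
    if not np.isin(gd, (0, 1)).all():
        raise ValueError("target must be binary")
    return pt, gd.astype(pd.dtype)


def tversky_loss(p, g, params: TverskyParams = TverskyParams()):
    """Tversky loss 1 - TP/(TP + alpha*FP + beta*FN), differentiable in p.

    ``p`` may be a plain array or an autodiff Tensor (gradients flow
    through it); ``g`` is the binary ground truth. The smoothing constant
    is added to numerator and denominator so empty-target patches are
    well defined.  Returns a scalar of the same kind as ``p``.
    """
    pt, gd = _prep(p, g)
    gc = constant(gd)
    tp = sum_all(pt * gc)
    fp = pt * constant(1.0 - gd)
    fn = (1.0 - pt) * gc
    if params.squared_penalties:
        fp = fp * fp
        fn = fn * fn
    den = tp + params.alpha * sum_all(fp) + params.beta * sum_all(fn)
    loss = 1.0 - (tp + params.smooth) / (den + params.smooth)
    return loss if isinstance(p, Tensor) else loss.item()


def dice_loss(p, g, smooth: float = 1e-6):
    """Dice loss 1 - 2|P.G|/(|P|+|G|); independent reference for alpha=beta=0.5."""
    pt, gd = _prep(p, g)
    pd = np.asarray(pt.data, dtype=float)
    num = 2.0 * float((pd * gd).sum()) + smooth
    den = float(pd.sum() + gd.sum()) + smooth
    return 1.0 - num / den


def ds_loss(main_loss, aux_losses, ds_alpha: float, use_ds: bool = True):
    """Combine head losses: L = L_main + ds_alpha * (L1 + L2 + L3).

    With deep supervision disabled the auxiliary list must be empty and
    the main loss is returned untouched.  Accepts floats or autodiff
    Tensors interchangeably.
    """
    aux_losses = list(aux_losses)
    if not use_ds:
        if aux_losses:
            raise ValueError("auxiliary losses supplied with deep supervision disabled")
        return main_loss
    if len(aux_losses) != 3:
        raise ValueError(f"deep supervision expects exactly 3 auxiliary losses, got {len(aux_losses)}")
    total = aux_losses[0]
    for a in aux_losses[1:]:
        total = total + a
    return main_loss + ds_alpha * total
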
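"""Training and sliding-window inference.

The training protocol: Adam, batch size 1 (one z-tile per step), initial
learning rate 1e-3 decayed by 0.1 at epochs 350 and 650, Tversky loss
(alpha/beta = 0.4/0.6) on every output head, deep-supervision combination
with a coefficient that decays by 0.8 every 40 epochs.  Cases are tiled
into fixed-depth z-patches sequentially (no random cropping), so a run
is a pure function of the seed.  Train/validation splits are made by
whole case, never by patch.

Inference tiles the (preprocessed) volume along z, averages overlapping
main-head probabilities, upsamples the probability field back to the
native grid trilinearly, and thresholds strictly at 0.5 (prob > 0.5 is
foreground).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .loss_sched import DSState, TverskyParams, ds_loss, lr_at_epoch, tversky_loss, update_ds_alpha
from .net import DAUNet, NetworkConfig, build_model
from .preprocess import PreprocessConfig, extract_patches, preprocess_pair, reassemble, resize_to_shape
from .volume import Mask, Volume

__all__ = [
    "TrainConfig",
    "Adam",
    "train",
    "split_cases",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 800
    base_lr: float = 0.001
    lr_milestones: tuple = (350, 650)
    gamma: float = 0.1
    seed: int = 0
    val_fraction: float = 0.0
    checkpoint_every: int = 0  # 0 = final checkpoint only
    stride_z: int = 16
    tversky: TverskyParams = field(default_factory=TverskyParams)
    ds: DSState = field(default_factory=DSState)
    net: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.lr_milestones = tuple(int(m) for m in self.lr_milestones)
        if any(m >= self.epochs for m in self.lr_milestones):
            # milestones beyond the run are harmless; inside-run ones must be sorted
            pass
        if list(self.lr_milestones) != sorted(self.lr_milestones):
            raise ValueError("lr_milestones must be ascending")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state(self):
        return {"m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v], "t": self.t}

    def load_state(self, state):
        self.m = [np.asarray(a).copy() for a in state["m"]]
        self.v = [np.asarray(a).copy() for a in state["v"]]
        self.t = int(state["t"])


def split_cases(n_cases: int, val_fraction: float, seed: int):
    """Deterministic whole-case split; returns (train_idx, val_idx)."""
    idx = np.arange(n_cases)
    n_val = int(round(n_cases * val_fraction))
    if n_val == 0:
        return list(idx), []
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx)
    return sorted(int(i) for i in perm[n_val:]), sorted(int(i) for i in perm[:n_val])


def _case_patches(image: np.ndarray, mask: np.ndarray, patch_shape, stride_z):
    pd = patch_shape[0]
    if image.shape[1:] != tuple(patch_shape[1:]):
        raise ValueError(
            f"case in-plane shape {image.shape[1:]} does not match patch {tuple(patch_shape[1:])}"
        )
    imgs, offs, pad = extract_patches(image, pd, stride_z)
    msks, _, _ = extract_patches(mask, pd, stride_z)
    return list(zip(imgs, msks)), offs, pad


def _heads_loss(out, gt_patch, tv: TverskyParams, ds_alpha: float, use_ds: bool):
    main = tversky_loss(out.main_prob, gt_patch, tv)
    aux = [tversky_loss(p, gt_patch, tv) for p in out.aux_probs]
    return ds_loss(main, aux, ds_alpha, use_ds=use_ds), main


def _eval_cases(model, cases, tv, stride_z):
    """Mean (loss, dice) of the main head over all patches of all cases."""
    losses, dices = [], []
    for image, mask in cases:
        patches, _, _ = _case_patches(image, mask, model.cfg.patch_shape, stride_z)
        for img_p, msk_p in patches:
            out = model.forward(img_p)
            prob = np.asarray(out.main_prob.data)
            losses.append(tversky_loss(prob, msk_p, tv))
            pred = prob > 0.5
            denom = pred.sum() + msk_p.sum()
            dices.append(1.0 if denom == 0 else 2.0 * (pred & (msk_p > 0)).sum() / denom)
    return float(np.mean(losses)), float(np.mean(dices))


def train(cases, cfg: TrainConfig, out_dir=None, model: DAUNet | None = None,
          resume_from=None):
    """Train on preprocessed (image, mask) array pairs.

    ``cases`` is a list of ``(image, mask)`` numpy pairs already brought
    to patch-compatible in-plane shape with intensities in [0, 1].
    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts
    (epoch, lr, ds_alpha, train_loss, train_dice, val_loss, val_dice)
    sufficient to plot loss/accuracy training curves.

    ``resume_from`` restores model parameters, optimizer moments and the
    epoch counter from a checkpoint; with fixed seeds the resumed run
    reproduces the uninterrupted loss trajectory.
    """
    cases = [(np.asarray(i, dtype=np.float32), np.asarray(m) > 0) for i, m in cases]
    start_epoch = 0
    opt_state = None
    if resume_from is not None:
        model, opt_state, start_epoch = _load_full_checkpoint(resume_from)
    elif model is None:
        model = build_model(cfg.net, seed=cfg.seed)
    tr_idx, va_idx = split_cases(len(cases), cfg.val_fraction, cfg.seed)
    train_cases = [cases[i] for i in tr_idx]
    val_cases = [cases[i] for i in va_idx]
    opt = Adam(model.parameters())
    if resume_from is not None and opt_state is not None:
        opt.load_state(opt_state)
    log = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(start_epoch, cfg.epochs):
        lr = lr_at_epoch(epoch, cfg.base_lr, cfg.lr_milestones, cfg.gamma)
        ds_state = update_ds_alpha(cfg.ds, epoch)
        ep_losses, ep_dices = [], []
        for image, mask in train_cases:
            patches, _, _ = _case_patches(image, mask, cfg.net.patch_shape, cfg.stride_z)
            for img_p, msk_p in patches:
                out = model.forward(img_p)
                loss, _ = _heads_loss(
                    out, msk_p, cfg.tversky, ds_state.ds_alpha, cfg.net.use_ds
                )
                lval = loss.item()
                if not np.isfinite(lval):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (lr={lr}, "
                        f"ds_alpha={ds_state.ds_alpha}); aborting"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step(lr)
                ep_losses.append(lval)
                prob = np.asarray(out.main_prob.data)
                pred = prob > 0.5
                denom = pred.sum() + msk_p.sum()
                ep_dices.append(
                    1.0 if denom == 0 else 2.0 * (pred & msk_p).sum() / denom
                )
        row = {
            "epoch": epoch,
            "lr": lr,
            "ds_alpha": ds_state.ds_alpha,
            "train_loss": float(np.mean(ep_losses)),
            "train_dice": float(np.mean(ep_dices)),
            "val_loss": float("nan"),
            "val_dice": float("nan"),
        }
        if val_cases:
            row["val_loss"], row["val_dice"] = _eval_cases(
                model, val_cases, cfg.tversky, cfg.stride_z
            )
        log.append(row)
        if out_dir is not None and cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(
                model, out_dir / f"checkpoint_{epoch:04d}.npz", cfg,
                optimizer=opt, epoch=epoch + 1,
            )

    if out_dir is not None:
        save_checkpoint(model, out_dir / "checkpoint_final.npz", cfg,
                        optimizer=opt, epoch=cfg.epochs)
        cols = ["epoch", "lr", "ds_alpha", "train_loss", "train_dice", "val_loss", "val_dice"]
        with open(out_dir / "training_log.tsv", "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in log:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return model, log


# ---------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------


def save_checkpoint(model: DAUNet, path, train_cfg: TrainConfig | None = None,
                    optimizer: Adam | None = None, epoch: int = 0):
    """Self-describing checkpoint: config, parameters, optimizer moments."""
    meta = {"net": model.cfg.to_dict(), "epoch": int(epoch)}
    if train_cfg is not None:
        meta["tversky"] = asdict(train_cfg.tversky)
        meta["ds"] = asdict(train_cfg.ds)
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    if optimizer is not None:
        meta["adam_t"] = optimizer.t
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            arrays[f"adam_m_{i:04d}"] = m
            arrays[f"adam_v_{i:04d}"] = v
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _load_full_checkpoint(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = [z[k] for k in sorted(k for k in z.files if k.startswith("param_"))]
        ms = [z[k] for k in sorted(k for k in z.files if k.startswith("adam_m_"))]
        vs = [z[k] for k in sorted(k for k in z.files if k.startswith("adam_v_"))]
    model = build_model(NetworkConfig.from_dict(meta["net"]))
    model.load_state_arrays(params)
    opt_state = {"m": ms, "v": vs, "t": meta.get("adam_t", 0)} if ms else None
    return model, opt_state, int(meta.get("epoch", 0))


def load_checkpoint(path) -> DAUNet:
    return _load_full_checkpoint(path)[0]


# ---------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------


def predict(model: DAUNet, vol: Volume, prep: PreprocessConfig | None = None,
            stride_z: int | None = None, preprocessed: bool = False,
            largest_component: bool = False):
    """Segment a volume; returns (probability Volume, Mask) on the native grid.

    With ``preprocessed=False`` the HU pipeline (window, z-resample,
    in-plane resize, [0,1] normalization — no span crop, since no ground
    truth exists at inference) is applied first.  The main-head
    probabilities of the z-tiles are averaged in overlaps, trilinearly
    upsampled back to the input grid, and thresholded strictly at 0.5.
    ``largest_component`` keeps only the largest 26-connected foreground
    component of the final mask (off by default).
    """
    prep = prep or PreprocessConfig(inplane_size=model.cfg.patch_shape[1])
    stride_z = stride_z or prep.stride_z
    native_shape = vol.shape
    if preprocessed:
        work = vol
    else:
        work, _, _ = preprocess_pair(vol, None, prep, crop=False)
    if work.shape[1:] != tuple(model.cfg.patch_shape[1:]):
        raise ValueError(
            f"preprocessed in-plane shape {work.shape[1:]} does not match "
            f"model patch {model.cfg.patch_shape[1:]}"
        )
    pd = model.cfg.patch_shape[0]
    patches, offs, pad = extract_patches(work.data, pd, stride_z)
    probs = [np.asarray(model.forward(p).main_prob.data)[0] for p in patches]
    prob = reassemble(probs, offs, work.shape[0], pad)
    prob_vol = Volume(prob, work.spacing_mm, vol.affine.copy())
    prob_native = resize_to_shape(prob_vol, native_shape, order=1)
    prob_native = prob_native.with_data(np.clip(prob_native.data, 0.0, 1.0), vol.spacing_mm)
    binary = prob_native.data > 0.5
    if largest_component and binary.any():
        from scipy import ndimage as ndi

        labels, n = ndi.label(binary, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
            binary = labels == (1 + int(np.argmax(sizes)))
    mask = Mask(binary.astype(np.uint8), vol.spacing_mm, vol.affine.copy())
    return prob_native, mask
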
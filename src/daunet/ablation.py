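"""The ablation ladder driver.

Trains four architecture variants with identical seeds and schedules —
plain 3D U-Net baseline, +Res (residual encoder), +AI (atrous-inception
bridge), +DS (deep supervision) — then evaluates each on held-out cases
with and without dense-CRF refinement, producing an 8-row summary table
(mean +/- sd of the five metrics per variant).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .crf import CRFParams, refine
from .metrics import evaluate_case
from .net import NetworkConfig, build_model
from .train import TrainConfig, predict, train
from .volume import Mask, Volume

__all__ = ["LADDER", "ladder_config", "run_ablation", "format_table"]

LADDER = (
    ("3D U-Net", dict(use_residual=False, use_ai=False, use_ds=False)),
    ("3D ResU-Net", dict(use_residual=True, use_ai=False, use_ds=False)),
    ("3D AI-UNet", dict(use_residual=True, use_ai=True, use_ds=False)),
    ("3D DA-UNet", dict(use_residual=True, use_ai=True, use_ds=True)),
)


def ladder_config(base: NetworkConfig, flags: dict) -> NetworkConfig:
    return replace(base, **flags)


def _summarize(reports):
    rows = np.array([r.row() for r in reports], dtype=float)
    return rows.mean(axis=0), rows.std(axis=0)


def run_ablation(train_cases, test_cases, base_cfg: TrainConfig,
                 crf_params: CRFParams | None = None, out_dir=None):
    """Train/evaluate the four ladder variants, each raw and +CRF.

    ``train_cases`` are preprocessed (image, mask) array pairs;
    ``test_cases`` are (Volume, Mask) pairs on the preprocessed grid.
    Returns a list of result dicts (one per variant x {raw, +CRF}); a
    variant whose training fails is recorded as a failed row and the run
    continues.
    """
    crf_params = crf_params or CRFParams(mode="approximate")
    results = []
    for name, flags in LADDER:
        cfg = replace(base_cfg, net=ladder_config(base_cfg.net, flags))
        try:
            model, log = train(train_cases, cfg)
        except Exception as exc:  # a failed variant must not sink the ladder
            for suffix in ("", " + CRF"):
                results.append({"model": name + suffix, "failed": str(exc)})
            continue
        raw_reports, crf_reports = [], []
        for vol, gt in test_cases:
            prob, pred = predict(model, vol, preprocessed=True)
            raw_reports.append(evaluate_case(pred, gt, vol.spacing_mm))
            refined = refine(prob, vol, crf_params)
            crf_reports.append(evaluate_case(refined, gt, vol.spacing_mm))
        for suffix, reports in (("", raw_reports), (" + CRF", crf_reports)):
            mean, sd = _summarize(reports)
            results.append(
                {
                    "model": name + suffix,
                    "n_parameters": model.n_parameters(),
                    "mean": mean.tolist(),
                    "sd": sd.tolist(),
                    "final_train_dice": log[-1]["train_dice"],
                }
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "ablation.tsv").write_text(format_table(results))
    return results


def format_table(results) -> str:
    """TSV table: one row per variant, Dice/VOE/RVD/ASD/RMSD as mean+/-sd."""
    cols = ["Dice", "VOE", "RVD", "ASD_mm", "RMSD_mm"]
    lines = ["model\tparams\t" + "\t".join(cols)]
    for r in results:
        if "failed" in r:
            lines.append(f"{r['model']}\tFAILED: {r['failed']}")
            continue
        cells = [
            f"{m:.4f}+/-{s:.4f}" for m, s in zip(r["mean"], r["sd"])
        ]
        lines.append(f"{r['model']}\t{r['n_parameters']}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
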
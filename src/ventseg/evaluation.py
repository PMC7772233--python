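"""Dice evaluation, grouped reporting and the three-regime ablation harness.

Reports follow the modality x thickness layout of clinical benchmark tables:
per-volume Dice plus group means for thick, thin and mixed (the union of the
two) within each modality.  Group means are volume-level — each volume
weighs equally regardless of its slice count, the clinically meaningful
unit — with a slice-pooled aggregate logged alongside for comparison.

The ablation harness trains three models from identical initialization:

* Exp 1 — supervised on labeled thick slices only (lambda = 0);
* Exp 2 — the divergence-to-uniform term alone on unlabeled thin slices,
  which collapses to confident single-class output (the regularizer's global
  minimum ignores anatomy entirely);
* Exp 3 — the combined semi-supervised objective.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import normalize, volume_to_samples
from .network import ModelConfig, SegModel, build_model
from .objectives import LossConfig
from .phantom import load_ground_truth, load_manifest, load_volume_row
from .trainer import TrainConfig, predict_volume, train
from .volume import Domain, LabeledVolume, Modality


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); both-empty counts as 1."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class DiceReport:
    """Per-volume Dice and group means in modality x thickness layout."""

    per_volume: list[tuple[str, str, str, float]]
    group_means: dict[tuple[str, str], float]
    slice_pooled_means: dict[tuple[str, str], float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_volume, columns=["volume_id", "modality", "domain", "dice"])

    def mean_dice(self) -> float:
        """Unweighted mean over all evaluated volumes."""
        return float(np.mean([r[3] for r in self.per_volume]))

    def render_table(self, label: str = "") -> str:
        mods = sorted({m for m, _ in self.group_means})
        header = f"{'':10s}" + "".join(
            f"{m + ' ' + g:>18s}" for m in mods for g in ("thick", "thin", "mixed"))
        vals = f"{label:10s}" + "".join(
            f"{self.group_means.get((m, g), float('nan')):>18.4f}"
            for m in mods for g in ("thick", "thin", "mixed"))
        return header + "\n" + vals


def _group_means(rows, slice_counts=None):
    means = {}
    mods = {m for _, m, _, _ in rows}
    for m in mods:
        for g in ("thick", "thin", "mixed"):
            sel = [
                (r, slice_counts[r[0]] if slice_counts else 1)
                for r in rows
                if r[1] == m and (g == "mixed" or r[2] == g)
            ]
            if sel:
                w = np.asarray([n for _, n in sel], dtype=float)
                d = np.asarray([r[3] for r, _ in sel])
                means[(m, g)] = float((d * w).sum() / w.sum())
    return means


def evaluate(model: SegModel, test_volumes: list[LabeledVolume],
             already_normalized: bool = False) -> DiceReport:
    """Per-volume Dice of model predictions against each volume's mask."""
    missing = [v.volume_id for v in test_volumes if v.mask is None]
    if missing:
        raise ValueError(f"test volumes without ground truth: {missing}")
    rows, slice_counts = [], {}
    for vol in test_volumes:
        norm = vol if already_normalized else normalize(vol)
        pred = predict_volume(model, norm)
        rows.append((vol.volume_id, vol.modality.value, vol.domain.value,
                     dice(pred.mask, vol.mask)))
        slice_counts[vol.volume_id] = vol.n_slices
    return DiceReport(
        per_volume=rows,
        group_means=_group_means(rows),
        slice_pooled_means=_group_means(rows, slice_counts),
    )


# ---------------------------------------------------------------------------
# Cohort plumbing


def load_cohort(manifest_path: str | Path):
    """Load a phantom cohort: labeled/unlabeled training samples and test
    volumes with their withheld ground truth attached."""
    df = load_manifest(manifest_path)
    root = df.attrs["root"]
    truth = load_ground_truth(manifest_path)
    labeled, unlabeled, test = [], [], []
    for _, row in df.iterrows():
        if row["split"] == "train":
            vol = load_volume_row(row, root, with_truth=False)
            samples = volume_to_samples(normalize(vol))
            if row["mask_path"]:
                labeled.extend(samples)
            else:
                unlabeled.extend(samples)
        elif row["split"] == "test":
            test.append(load_volume_row(row, root, with_truth=True, truth=truth))
    return labeled, unlabeled, test


# ---------------------------------------------------------------------------
# Ablation harness


def run_ablation(manifest_path: str | Path, model_config: ModelConfig,
                 train_config: TrainConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Run the thick-only / thin-only / combined experiments.

    All three share the initialization seed, architecture, cohort and
    training schedule; only the data regime and lambda differ.  Returns
    ``{"exp1": DiceReport, "exp2": ..., "exp3": ..., "table": str}`` and, if
    ``out_dir`` is given, writes per-experiment CSV reports, checkpoints and
    the side-by-side comparison table.
    """
    labeled, unlabeled, test = load_cohort(manifest_path)
    # Exp 2's epoch anchor is the (typically much larger) unlabeled set; cap
    # its epochs so all three regimes run a comparable number of steps.
    lab_steps = int(np.ceil(len(labeled) / train_config.labeled_batch))
    unl_steps = int(np.ceil(len(unlabeled) / train_config.unlabeled_batch))
    exp2_epochs = max(1, int(round(train_config.epochs * lab_steps / max(unl_steps, 1))))
    regimes = {
        "exp1": (labeled, [], replace(train_config.loss, lambda_weight=0.0),
                 train_config.epochs),
        "exp2": ([], unlabeled, train_config.loss, exp2_epochs),
        "exp3": (labeled, unlabeled, train_config.loss, train_config.epochs),
    }
    out_dir = Path(out_dir) if out_dir is not None else None
    reports: dict = {}
    for name, (lab, unl, loss_cfg, epochs) in regimes.items():
        ckpt_dir = None if out_dir is None else out_dir / name
        cfg = replace(train_config, loss=loss_cfg, checkpoint_dir=ckpt_dir,
                      epochs=epochs)
        model = build_model(model_config)
        model, _ = train(model, lab, unl, cfg)
        reports[name] = evaluate(model, test)

    lines = [
        reports["exp1"].render_table("Exp 1"),
        reports["exp2"].render_table("Exp 2").splitlines()[1],
        reports["exp3"].render_table("Exp 3").splitlines()[1],
    ]
    table = "\n".join(lines) + "\n"
    reports["table"] = table
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("exp1", "exp2", "exp3"):
            reports[name].to_frame().to_csv(out_dir / f"{name}_dice.csv", index=False)
        (out_dir / "ablation_table.txt").write_text(table)
    return reports


def thin_dice_gain(reports: dict) -> float:
    """Exp 3 minus Exp 1 mean thin-slice Dice, in percentage points."""

    def thin_mean(rep: DiceReport) -> float:
        vals = [r[3] for r in rep.per_volume if r[2] == Domain.THIN.value]
        return float(np.mean(vals))

    return 100.0 * (thin_mean(reports["exp3"]) - thin_mean(reports["exp1"]))
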
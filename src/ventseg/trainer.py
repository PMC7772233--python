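"""Semi-supervised training loop and whole-volume inference.

Each optimization step draws one batch of labeled thick-slice samples and one
batch of unlabeled thin-slice samples, evaluates the combined objective
``L_S + lambda * L_T`` on the pair, and applies a single optimizer update
(joint pairing; an alternating mode applying the two parts as separate
updates is available for comparison).  One epoch is one pass over the labeled
set; the unlabeled set cycles with reshuffling since the two sets generally
differ in size.

Degenerate regimes are first-class: an empty unlabeled set (or lambda = 0)
reduces to plain supervised training, and an empty labeled set with
lambda > 0 trains on the divergence-to-uniform term alone — useful only to
demonstrate that unlabeled training collapses to confident nonsense.

``lambda`` follows a linear warm-up over the first ``warmup_frac`` of steps:
entropy-type regularizers applied at full strength from step 0 can lock in a
collapsed solution before the supervised term shapes the features.

Runs are reproducible: all shuffling derives from ``config.seed`` through
independent named streams, so a config + seed fully determines the parameter
trajectory, the training log and the final checkpoint.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import volume_to_samples
from .network import SegModel
from .nn import Adam, SGD, softmax, softmax_backward
from .objectives import (LossConfig, supervised_loss, supervised_loss_grad,
                         target_loss, target_loss_grad)
from .volume import LabeledVolume, SliceSample


class ConfigurationError(ValueError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 16
    labeled_batch: int = 8
    unlabeled_batch: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    checkpoint_dir: str | Path | None = None
    warmup_frac: float = 0.1
    pairing: str = "joint"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if min(self.labeled_batch, self.unlabeled_batch) < 1:
            raise ConfigurationError("batch sizes must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.pairing not in ("joint", "alternating"):
            raise ConfigurationError(f"unknown pairing {self.pairing!r}")
        if not (0.0 <= self.warmup_frac <= 1.0):
            raise ConfigurationError("warmup_frac must be in [0, 1]")


@dataclass
class TrainHistory:
    """Per-step records (step, L_S, L_T, total, lambda_effective)."""

    records: list[tuple[int, float, float, float, float]]
    checkpoint_path: Path | None = None

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "loss_supervised", "loss_target", "loss_total",
                        "lambda_effective"])
            for rec in self.records:
                w.writerow([rec[0]] + [f"{v:.8f}" for v in rec[1:]])


def _stack(samples: list[SliceSample], with_labels: bool):
    x = np.stack([s.image for s in samples]).transpose(0, 3, 1, 2)
    if not with_labels:
        return np.ascontiguousarray(x, dtype=np.float32), None
    y = np.stack([s.label for s in samples]).astype(np.int64)
    return np.ascontiguousarray(x, dtype=np.float32), y


class _Cycler:
    """Endless reshuffling iterator over a sample list."""

    def __init__(self, items, batch: int, rng: np.random.Generator):
        self.items, self.batch, self.rng = items, batch, rng
        self.order = []

    def next_batch(self):
        while len(self.order) < self.batch:
            self.order.extend(self.rng.permutation(len(self.items)).tolist())
        take, self.order = self.order[: self.batch], self.order[self.batch:]
        return [self.items[i] for i in take]


def train(model: SegModel, labeled: list[SliceSample],
          unlabeled: list[SliceSample], config: TrainConfig
          ) -> tuple[SegModel, TrainHistory]:
    """Optimize the combined objective; returns the model and its history."""
    labeled = [s for s in labeled if s.label is not None]
    if not labeled and not unlabeled:
        raise ConfigurationError("both the labeled and unlabeled sets are empty")
    if not labeled and config.loss.lambda_weight == 0:
        raise ConfigurationError(
            "no labeled samples and lambda = 0: nothing to optimize")

    ss = np.random.SeedSequence([config.seed, 0x7A11])
    rng_l, rng_u = (np.random.default_rng(c) for c in ss.spawn(2))

    opt_cls = {"adam": Adam, "sgd": SGD}[config.optimizer]
    opt = opt_cls(model.layers(), lr=config.learning_rate)

    anchor = labeled if labeled else unlabeled
    anchor_batch = config.labeled_batch if labeled else config.unlabeled_batch
    steps_per_epoch = int(np.ceil(len(anchor) / anchor_batch))
    total_steps = config.epochs * steps_per_epoch
    warmup_steps = max(int(round(config.warmup_frac * total_steps)), 0)

    lab_cycler = _Cycler(labeled, config.labeled_batch, rng_l) if labeled else None
    unl_cycler = _Cycler(unlabeled, config.unlabeled_batch, rng_u) if unlabeled else None

    model.set_training(True)
    records = []
    for step in range(total_steps):
        lam = config.loss.lambda_weight
        if warmup_steps and lam > 0:
            lam *= min(1.0, (step + 1) / warmup_steps)

        opt.zero_grad()
        l_s = 0.0
        if lab_cycler:
            x, y = _stack(lab_cycler.next_batch(), with_labels=True)
            logits = model.forward_logits(x)
            p = softmax(logits, axis=1).transpose(0, 2, 3, 1)
            l_s = supervised_loss(p, y)
            dp = supervised_loss_grad(p, y)
            model.backward(softmax_backward(p, dp, axis=3).transpose(0, 3, 1, 2))
            if config.pairing == "alternating":
                opt.step()
                opt.zero_grad()

        l_t = 0.0
        did_unlabeled = False
        if unl_cycler and lam > 0:
            x, _ = _stack(unl_cycler.next_batch(), with_labels=False)
            logits = model.forward_logits(x)
            p = softmax(logits, axis=1).transpose(0, 2, 3, 1)
            l_t = target_loss(p, config.loss.divergence)
            dp = lam * target_loss_grad(p, config.loss.divergence)
            model.backward(softmax_backward(p, dp, axis=3).transpose(0, 3, 1, 2))
            did_unlabeled = True
        if config.pairing == "joint" or did_unlabeled:
            opt.step()

        records.append((step, float(l_s), float(l_t),
                        float(l_s + lam * l_t), float(lam)))

    history = TrainHistory(records)
    if config.checkpoint_dir is not None:
        out = Path(config.checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt = out / "model.npz"
        model.save(ckpt)
        history.checkpoint_path = ckpt
        history.write_csv(out / "training_log.csv")
    return model, history


def predict_volume(model: SegModel, volume: LabeledVolume,
                   chunk: int = 8) -> LabeledVolume:
    """Segment a normalized volume slice-by-slice and restack the mask.

    Spatial dims that are not multiples of the encoder stride are padded for
    the forward pass and cropped back, so the predicted mask always matches
    the input shape exactly.
    """
    samples = volume_to_samples(volume)
    preds = []
    for i in range(0, len(samples), chunk):
        x, _ = _stack(samples[i : i + chunk], with_labels=False)
        p = model.forward_proba_batch(x)
        preds.append(p.argmax(axis=1).astype(np.uint8))
    mask = np.concatenate(preds, axis=0)
    meta = dict(volume.meta)
    meta["predicted"] = True
    return LabeledVolume(
        intensity=volume.intensity, spacing=volume.spacing,
        modality=volume.modality, volume_id=volume.volume_id,
        mask=mask, meta=meta,
    )
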
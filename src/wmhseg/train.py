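"""Ensemble training with cosine-annealed Adam and the pseudo-labeling stage.

Training iterates all slices of every training case — lesion-free slices
included — in seeded shuffled batches, augments each slice, and minimises
the MCC loss computed jointly over the whole batch (matching the
global-count structure of the Matthews coefficient). Defaults follow the
reference protocol: Adam, learning rate 0.001 decayed by cosine annealing
to 0, batch size 15, 15 epochs, no validation split or early stopping.

Pseudo-labeling: a trained ensemble predicts binary masks for every
unlabeled case; all predictions are kept (no confidence filtering) and the
union of labeled and pseudo-labeled cases, weighted equally, trains a new
ensemble. A leakage guard refuses pseudo cases that overlap the test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, apply_augmentations
from .io import CaseManifest, LesionMask, ManifestEntry, load_case, save_mask
from .model import EnsembleModel, MemberSpec, binarize, build_member, mcc_loss, predict_volume
from .nn import Adam, Tensor, trim_memory
from .preprocess import normalize_volume, resize_mask_slice, resize_slice

__all__ = [
    "TrainConfig",
    "PseudoLabelSet",
    "cosine_lr",
    "train_member",
    "train_ensemble",
    "generate_pseudo_labels",
    "train_with_pseudo",
]


def _default_members():
    return [
        MemberSpec(encoder_family="resnext"),
        MemberSpec(encoder_family="efficientnet"),
    ]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 15
    epochs: int = 15
    floor_lr: float = 0.0
    warmup_steps: int = 10
    seed: int = 0
    members: list = field(default_factory=_default_members)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    deterministic: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be at least 1")
        if self.floor_lr > self.learning_rate:
            raise ValueError("floor_lr cannot exceed the base learning rate")

    def config_hash(self) -> str:
        import hashlib
        parts = [repr(self.__dict__)]
        return hashlib.sha1("".join(parts).encode()).hexdigest()[:12]


@dataclass
class PseudoLabelSet:
    """Model-predicted masks for unlabeled cases, with generating-model provenance."""

    entries: list = field(default_factory=list)  # (case_id, pseudo_mask_path)
    provenance: str = ""

    def case_ids(self):
        return [cid for cid, _ in self.entries]


def cosine_lr(epoch_progress: float, base_lr: float, floor_lr: float = 0.0) -> float:
    """Cosine-annealing schedule: base at progress 0, floor at progress 1."""
    if not (0.0 <= epoch_progress <= 1.0):
        raise ValueError("epoch_progress must lie in [0, 1]")
    if floor_lr > base_lr:
        raise ValueError("floor_lr cannot exceed base_lr")
    return floor_lr + 0.5 * (base_lr - floor_lr) * (1.0 + math.cos(math.pi * epoch_progress))


def _load_training_slices(manifest: CaseManifest, input_size: int, roles=("train", "pseudo")):
    """All slices of all training-role cases, resized to the model grid."""
    images, masks, case_ids = [], [], []
    for entry in manifest.entries:
        if entry.role not in roles:
            continue
        volume, mask = load_case(entry.volume_path, entry.mask_path)
        volume = normalize_volume(volume)
        for z in range(volume.intensities.shape[0]):
            images.append(resize_slice(volume.intensities[z], (input_size, input_size)))
            masks.append(resize_mask_slice(mask.labels[z], (input_size, input_size)))
            case_ids.append(entry.case_id)
    if not images:
        raise ValueError("no labeled training slices in manifest")
    return np.stack(images), np.stack(masks), case_ids


@dataclass
class TrainLog:
    """Per-epoch mean loss / lr and the case-id audit trail of every batch."""

    epochs: list = field(default_factory=list)  # (epoch, mean_loss, last_lr)
    batch_case_ids: list = field(default_factory=list)

    def write(self, path):
        with open(path, "w") as fh:
            fh.write("epoch\tmean_loss\tlr\n")
            for epoch, loss, lr in self.epochs:
                fh.write(f"{epoch}\t{loss:.6f}\t{lr:.6g}\n")


def train_member(spec: MemberSpec, manifest: CaseManifest, config: TrainConfig):
    """Train one U-Net member; returns (member, TrainLog)."""
    images, masks, case_ids = _load_training_slices(manifest, spec.input_size)
    n = len(images)
    member = build_member(spec)
    optimizer = Adam(member.parameters(), lr=config.learning_rate * spec.lr_scale)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, spec.seed, 7)))
    n_batches = max(1, math.ceil(n / config.batch_size))
    total_steps = config.epochs * n_batches
    log = TrainLog()
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        lr = config.learning_rate
        for b in range(n_batches):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            batch_x = np.empty((len(idx), spec.input_size, spec.input_size, 1), dtype=np.float32)
            batch_y = np.empty((len(idx), spec.input_size, spec.input_size, 1), dtype=np.float32)
            for j, i in enumerate(idx):
                img, msk = apply_augmentations(images[i], masks[i], config.augment, rng)
                batch_x[j, ..., 0] = img
                batch_y[j, ..., 0] = msk
            log.batch_case_ids.append(sorted({case_ids[i] for i in idx}))
            lr = cosine_lr(step / max(1, total_steps - 1), config.learning_rate, config.floor_lr)
            if config.warmup_steps > 0 and step < config.warmup_steps:
                # linear warmup guards against an early overshoot into the
                # all-background dead zone of the MCC loss
                lr *= (step + 1) / config.warmup_steps
            optimizer.lr = lr * spec.lr_scale
            pred = member(Tensor(batch_x))
            loss = mcc_loss(pred, batch_y)
            value = loss.item()
            if not math.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch {b + 1} "
                    f"(lr={lr:.3g}); aborting training"
                )
            member.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(value)
            step += 1
        trim_memory()
        log.epochs.append((epoch + 1, float(np.mean(losses)), lr))
    member.eval()
    return member, log


def train_ensemble(config: TrainConfig, manifest: CaseManifest):
    """Train every member independently (distinct seeds) and fuse by mean.

    Returns (EnsembleModel, list of TrainLog).
    """
    members, logs = [], []
    for i, spec in enumerate(config.members):
        member_spec = replace(spec, seed=config.seed + 1000 * i + spec.seed)
        member, log = train_member(member_spec, manifest, config)
        members.append(member)
        logs.append(log)
    return EnsembleModel(members=members), logs


def generate_pseudo_labels(model: EnsembleModel, manifest: CaseManifest, out_dir, provenance: str = "") -> PseudoLabelSet:
    """Predict binary masks for every unlabeled case; keep all of them.

    Pseudo-annotations inevitably mix correct and incorrect predictions; no
    confidence filtering is applied.
    """
    unlabeled = manifest.by_role("unlabeled")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pseudo = PseudoLabelSet(provenance=provenance)
    for entry in unlabeled:
        volume, _ = load_case(entry.volume_path)
        probs = predict_volume(model, normalize_volume(volume))
        mask = LesionMask(binarize(probs, model.threshold), volume.spacing_mm, volume.case_id)
        path = out_dir / f"{entry.case_id}_pseudo.nii.gz"
        save_mask(mask, path)
        pseudo.entries.append((entry.case_id, str(path)))
    return pseudo


def train_with_pseudo(config: TrainConfig, manifest: CaseManifest, pseudo: PseudoLabelSet):
    """Retrain on labeled-train plus pseudo-labeled cases, equally weighted."""
    if not pseudo.entries:
        raise ValueError("pseudo-label set is empty")
    test_ids = {e.case_id for e in manifest.by_role("test")}
    train_ids = {e.case_id for e in manifest.by_role("train")}
    overlap = test_ids & set(pseudo.case_ids())
    if overlap:
        raise ValueError(f"pseudo-label leakage into test split: {sorted(overlap)}")
    if train_ids & set(pseudo.case_ids()):
        raise ValueError("pseudo cases must be disjoint from labeled train cases")
    pseudo_paths = dict(pseudo.entries)
    entries = []
    for e in manifest.entries:
        if e.case_id in pseudo_paths:
            entries.append(ManifestEntry(
                case_id=e.case_id, role="pseudo", volume_path=e.volume_path,
                mask_path=pseudo_paths[e.case_id], spacing_mm=e.spacing_mm,
            ))
        else:
            entries.append(e)
    return train_ensemble(config, CaseManifest(entries))
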
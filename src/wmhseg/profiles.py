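"""Named run profiles: ``desk`` (CPU-sized) and ``full`` (reference-scale).

The full profile mirrors the reference training protocol: 512x512 model
grid, Adam at learning rate 0.001 with cosine annealing, batch 15, 15
epochs, the standard augmentation suite, and two members (ResNeXt-style
and EfficientNet-style encoders). The desk profile keeps the identical
pipeline topology but shrinks everything to run on one CPU core in
minutes: 128x128 phantoms and model grid, channel-reduced members, 5
epochs, a higher base learning rate with warmup (appropriate to the ~70
optimisation steps available at this scale), and lighter augmentation
magnitudes. Every field can be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .augment import AugmentConfig
from .model import MemberSpec
from .phantom import PhantomConfig
from .train import TrainConfig

__all__ = ["RunConfig", "desk_members", "full_members", "desk_train_config",
           "full_train_config", "desk_phantom_config", "load_run_config"]

PROFILES = ("desk", "full")


def desk_members(input_size: int = 128):
    return [
        MemberSpec("resnext", base_channels=8, depth=3, groups=4, input_size=input_size, lr_scale=1.0),
        MemberSpec("efficientnet", base_channels=12, depth=3, expansion=2, input_size=input_size, lr_scale=1.5),
    ]


def full_members():
    return [
        MemberSpec("resnext", base_channels=32, depth=4, groups=8, input_size=512, lr_scale=1.0),
        MemberSpec("efficientnet", base_channels=24, depth=4, expansion=4, input_size=512, lr_scale=1.0),
    ]


def desk_augment_config() -> AugmentConfig:
    return AugmentConfig(shift_frac_max=0.05, rotate_deg_max=10.0, grid_p=0.3)


def desk_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        learning_rate=0.02, batch_size=15, epochs=5, seed=seed,
        members=desk_members(), augment=desk_augment_config(),
    )


def full_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        learning_rate=0.001, batch_size=15, epochs=15, seed=seed,
        members=full_members(), augment=AugmentConfig(),
    )


def desk_phantom_config(seed: int = 0, n_cases: int = 30) -> PhantomConfig:
    return PhantomConfig(seed=seed, n_cases=n_cases)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see the ``run`` CLI command)."""

    profile: str = "desk"
    seed: int = 0
    out_dir: str = "wmhseg_run"
    n_cases: int = 30
    split: tuple = (0.5, 0.2, 0.3)
    with_pseudo: bool = True
    force: bool = False
    phantom: dict = field(default_factory=dict)   # PhantomConfig overrides
    train: dict = field(default_factory=dict)     # TrainConfig overrides
    augment: dict = field(default_factory=dict)   # AugmentConfig overrides

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}")

    def phantom_config(self) -> PhantomConfig:
        base = desk_phantom_config(self.seed, self.n_cases)
        return replace(base, **self.phantom)

    def train_config(self) -> TrainConfig:
        base = desk_train_config(self.seed) if self.profile == "desk" else full_train_config(self.seed)
        if self.augment:
            base = replace(base, augment=replace(base.augment, **self.augment))
        return replace(base, **self.train)

    def to_yaml(self, path):
        def plain(obj):
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [plain(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(asdict(self)), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "split" in raw:
        raw["split"] = tuple(raw["split"])
    return RunConfig(**raw)
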
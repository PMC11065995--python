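"""The two-member 2D U-Net ensemble, MCC loss, inference and binarization.

The segmentation network is a slice-wise U-Net whose encoder comes in two
flavours mirroring the two ensemble members: a grouped-convolution residual
encoder (``resnext`` family) and a depthwise-separable encoder
(``efficientnet`` family). Member capacity is set by ``base_channels`` and
``depth`` so the same topology scales from a CPU-sized desk profile to
larger configurations.

The loss is one minus a soft Matthews correlation coefficient computed from
soft confusion counts over the whole batch; it penalises errors on both the
lesion and background classes, which matters when lesions occupy a tiny
fraction of the slice.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .io import FlairVolume, LesionMask
from .preprocess import resize_slice, restore_prediction

__all__ = [
    "MemberSpec",
    "EnsembleModel",
    "build_member",
    "mcc_loss",
    "soft_confusion",
    "predict_volume",
    "binarize",
    "save_checkpoint",
    "load_checkpoint",
]

MCC_EPS = 1e-7

ENCODER_FAMILIES = ("resnext", "efficientnet")


@dataclass
class MemberSpec:
    """Architecture description of one ensemble member.

    ``encoder_family`` selects the block type: ``resnext`` uses grouped
    3x3 convolutions with residual connections; ``efficientnet`` uses
    depthwise-separable (depthwise 3x3 + pointwise 1x1) blocks.
    ``use_pretrained_init`` is accepted for configuration parity but this
    framework ships no pretrained weight zoo, so it must stay False;
    initialisation is seeded He-normal.
    """

    encoder_family: str = "resnext"
    base_channels: int = 8
    depth: int = 3
    groups: int = 4
    expansion: int = 2
    lr_scale: float = 1.0
    use_pretrained_init: bool = False
    input_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.encoder_family not in ENCODER_FAMILIES:
            raise ValueError(f"unknown encoder family {self.encoder_family!r}")
        if self.use_pretrained_init:
            raise ValueError("no pretrained weights are available in this build; "
                             "set use_pretrained_init=False for seeded random init")
        if self.input_size % (2 ** self.depth):
            raise ValueError("input_size must be divisible by 2**depth")


class _ResNeXtBlock(nn.Module):
    """Double grouped-3x3 conv with a residual shortcut (1x1 projection on width change)."""

    def __init__(self, cin, cout, groups, rng):
        super().__init__()
        g1 = groups if (cout % groups == 0 and cin % groups == 0) else 1
        g2 = groups if cout % groups == 0 else 1
        self.conv1 = nn.Conv2d(cin, cout, 3, groups=g1, bias=False, rng=rng)
        self.n1 = nn.InstanceNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, groups=g2, bias=False, rng=rng)
        self.n2 = nn.InstanceNorm2d(cout)
        self.proj = None if cin == cout else nn.Conv2d(cin, cout, 1, bias=False, rng=rng)

    def __call__(self, x):
        y = self.n1(self.conv1(x)).relu()
        y = self.n2(self.conv2(y))
        s = x if self.proj is None else self.proj(x)
        return (y + s).relu()


class _MBConvBlock(nn.Module):
    """Inverted residual: pointwise expand, depthwise 3x3, pointwise project.

    MBConv without squeeze-excite; residual shortcut when the width allows.
    """

    def __init__(self, cin, cout, expansion, rng):
        super().__init__()
        # expansion is capped at twice the output width so decoder blocks
        # (wide concatenated inputs, narrow outputs) stay affordable on CPU
        mid = max(cout, min(cin * expansion, 2 * cout))
        self.expand = nn.Conv2d(cin, mid, 1, bias=False, rng=rng)
        self.n1 = nn.InstanceNorm2d(mid)
        self.dw = nn.Conv2d(mid, mid, 3, groups=mid, bias=False, rng=rng)
        self.n2 = nn.InstanceNorm2d(mid)
        self.project = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.n3 = nn.InstanceNorm2d(cout)
        self.residual = cin == cout

    def __call__(self, x):
        y = self.n1(self.expand(x)).relu()
        y = self.n2(self.dw(y)).relu()
        y = self.n3(self.project(y))
        if self.residual:
            y = y + x
        return y.relu()


class UNet(nn.Module):
    """Slice-wise U-Net: encoder blocks per level, nearest-up decoder with skips."""

    def __init__(self, spec: MemberSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        chans = [spec.base_channels * (2 ** i) for i in range(spec.depth + 1)]

        def block(cin, cout):
            if spec.encoder_family == "resnext":
                return _ResNeXtBlock(cin, cout, spec.groups, rng)
            return _MBConvBlock(cin, cout, spec.expansion, rng)

        self.enc = [block(1 if i == 0 else chans[i - 1], chans[i]) for i in range(spec.depth)]
        self.bottleneck = block(chans[spec.depth - 1], chans[spec.depth])
        # decoder convs take upsampled features concatenated with the skip
        self.dec = [block(chans[i + 1] + chans[i], chans[i]) for i in reversed(range(spec.depth))]
        self.head = nn.Conv2d(chans[0], 1, 1, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        # x is channels-last: (batch, H, W, 1)
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        x = self.bottleneck(x)
        for blk, skip in zip(self.dec, reversed(skips)):
            x = nn.concat([nn.upsample2x(x), skip], axis=-1)
            x = blk(x)
        return self.head(x).sigmoid()

    def predict_slices(self, slices: np.ndarray) -> np.ndarray:
        """Probability maps for a (n, H, W) stack at model resolution (eval mode)."""
        was_training = self.training
        self.eval()
        out = self(nn.Tensor(slices[..., None].astype(np.float32))).data[..., 0]
        self.train(was_training)
        return np.asarray(out, dtype=np.float32)


def build_member(spec: MemberSpec) -> UNet:
    return UNet(spec)


# -- MCC loss --------------------------------------------------------------


def soft_confusion(pred, target):
    """Soft confusion masses (tp, fp, fn, tn) from probabilities and binary targets.

    With hard 0/1 predictions these reduce exactly to voxel counts.
    """
    p = pred if isinstance(pred, nn.Tensor) else nn.Tensor(np.asarray(pred, dtype=np.float64))
    t = np.asarray(target, dtype=p.data.dtype)
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("target must be binary")
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.data.shape} vs target {t.shape}")
    tt = nn.Tensor(t)
    ct = nn.Tensor(1.0 - t)
    cp = 1.0 - p
    tp = (p * tt).sum()
    fp = (p * ct).sum()
    fn = (cp * tt).sum()
    tn = (cp * ct).sum()
    return tp, fp, fn, tn


def mcc_loss(pred, target, eps: float = MCC_EPS):
    """1 - soft Matthews correlation coefficient; in [0, 2], differentiable.

    The small ``eps`` stabilises the degenerate cases: it sits in both the
    numerator and denominator, so perfect agreement — including an
    all-background prediction on an all-background target — gives exactly
    zero loss, while a prediction independent of the target gives loss 1.

    Returns a ``wmhseg.nn.Tensor`` when ``pred`` is one (for backprop),
    otherwise a float.
    """
    tensor_in = isinstance(pred, nn.Tensor)
    tp, fp, fn, tn = soft_confusion(pred, target)
    num = tp * tn - fp * fn + eps
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)).sqrt() + eps
    loss = 1.0 - num / den
    return loss if tensor_in else loss.item()


# -- ensemble --------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Trained members fused by voxel-wise probability averaging, one 0.5 threshold."""

    members: list = field(default_factory=list)
    threshold: float = 0.5

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def input_size(self) -> int:
        return self.members[0].spec.input_size


def predict_volume(model: EnsembleModel, volume: FlairVolume) -> np.ndarray:
    """Slice-wise ensemble probabilities restored to the native grid.

    The volume must already be normalized to [0, 1]. Each slice is resized
    to the model resolution, run through every member, the member
    probabilities are averaged voxel-wise, and the fused map is restored to
    the native slice shape.
    """
    if volume.intensities.size == 0:
        raise ValueError("empty volume")
    lo, hi = float(volume.intensities.min()), float(volume.intensities.max())
    if lo < -1e-6 or hi > 1 + 1e-6:
        raise ValueError("predict_volume expects a volume normalized to [0, 1]")
    size = model.input_size
    native_shape = volume.intensities.shape[1:]
    stack = np.stack(
        [resize_slice(s, (size, size)) for s in volume.intensities.astype(np.float32)]
    )
    fused = np.zeros_like(stack, dtype=np.float64)
    for member in model.members:
        fused += member.predict_slices(stack)
    fused /= len(model.members)
    restored = np.stack([restore_prediction(p, native_shape) for p in fused])
    return np.clip(restored, 0.0, 1.0).astype(np.float32)


def binarize(probs: np.ndarray, threshold: float = 0.5, *, spacing_mm=None, case_id: str = "") -> np.ndarray:
    """Threshold a probability map; ties at the threshold go to foreground."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    probs = np.asarray(probs)
    if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(np.uint8)


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path, model: EnsembleModel, train_config_hash: str = ""):
    """Single-file archive: member weights + specs + training config hash."""
    arrays = {}
    specs = []
    for i, member in enumerate(model.members):
        specs.append(asdict(member.spec))
        for k, v in member.state_dict().items():
            arrays[f"member{i}.{k}"] = v
    meta = json.dumps({
        "specs": specs,
        "threshold": model.threshold,
        "train_config_hash": train_config_hash,
        "format_version": 1,
    })
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> EnsembleModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        members = []
        for i, spec_dict in enumerate(meta["specs"]):
            spec = MemberSpec(**spec_dict)
            member = build_member(spec)
            prefix = f"member{i}."
            state = {k[len(prefix):]: archive[k] for k in archive.files if k.startswith(prefix)}
            member.load_state_dict(state)
            members.append(member)
    return EnsembleModel(members=members, threshold=meta["threshold"])


def checkpoint_hash(path) -> str:
    """Stable content hash of a checkpoint file (provenance for pseudo-labels)."""
    with open(path, "rb") as fh:
        return format(zlib.crc32(fh.read()) & 0xFFFFFFFF, "08x")
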
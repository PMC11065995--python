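"""Volume / mask / manifest I-O and geometric consistency checks.

Conventions: arrays are (slice, row, column) with spacing (dz, dy, dx) in
mm — the slice axis is the thick (5-6 mm) axis. NIfTI files store data in
(x, y, z) order, so arrays are transposed on read/write; orientation
beyond voxel spacing is ignored (phantoms are axis-aligned, real data must
be pre-oriented). Masks are unsigned 8-bit {0,1}; any nonzero label is
binarized to 1 on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FlairVolume",
    "LesionMask",
    "ManifestEntry",
    "CaseManifest",
    "load_case",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "read_manifest",
    "write_manifest",
    "split_manifest",
]

ROLES = ("train", "test", "unlabeled", "pseudo")


@dataclass
class FlairVolume:
    """3D FLAIR intensities with physical voxel spacing and case identity."""

    intensities: np.ndarray  # (n_slices, height, width)
    spacing_mm: tuple  # (dz, dy, dx)
    case_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("volume must be 3D (n_slices, height, width)")
        if self.intensities.shape[0] < 1:
            raise ValueError("volume needs at least one slice")
        if not np.isfinite(self.intensities).all():
            raise ValueError("volume intensities must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive components (dz, dy, dx)")


@dataclass
class LesionMask:
    """Binary lesion labels aligned to a FlairVolume."""

    labels: np.ndarray
    spacing_mm: tuple
    case_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3D (n_slices, height, width)")
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive components (dz, dy, dx)")


@dataclass
class ManifestEntry:
    case_id: str
    role: str
    volume_path: str
    mask_path: str = ""  # empty for unlabeled cases
    spacing_mm: tuple = (5.0, 1.0, 1.0)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class CaseManifest:
    """Dataset ledger: one entry per case, roles train/test/unlabeled/pseudo."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        ids = [e.case_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("case_ids must be unique")
        for e in self.entries:
            if e.role in ("train", "test", "pseudo") and not e.mask_path:
                raise ValueError(f"{e.role} case {e.case_id} needs a mask path")

    def by_role(self, role: str) -> list:
        return [e for e in self.entries if e.role == role]

    def __len__(self):
        return len(self.entries)


# -- NIfTI round trip -------------------------------------------------------


def _to_nifti(array: np.ndarray, spacing_mm) -> nib.Nifti1Image:
    dz, dy, dx = spacing_mm
    # array (z, y, x) -> NIfTI canonical (x, y, z)
    data = np.ascontiguousarray(array.transpose(2, 1, 0))
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    return img


def _from_nifti(img: nib.Nifti1Image):
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    dx, dy, dz = (float(z) for z in zooms)
    if min(dx, dy, dz) <= 0:
        raise ValueError("voxel spacing must be positive")
    return data.transpose(2, 1, 0), (dz, dy, dx)


def save_volume(volume: FlairVolume, path):
    img = _to_nifti(volume.intensities.astype(np.float32), volume.spacing_mm)
    nib.save(img, str(path))


def save_mask(mask: LesionMask, path):
    img = _to_nifti(mask.labels.astype(np.uint8), mask.spacing_mm)
    nib.save(img, str(path))


def load_volume(path) -> FlairVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing = _from_nifti(nib.load(str(path)))
    return FlairVolume(np.asarray(data, dtype=np.float32), spacing, case_id=_case_id_from(path))


def load_mask(path) -> LesionMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing = _from_nifti(nib.load(str(path)))
    return LesionMask((np.asarray(data) != 0).astype(np.uint8), spacing, case_id=_case_id_from(path))


def _case_id_from(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def load_case(volume_path, mask_path=None):
    """Load a volume and (optionally) its mask; shape mismatch is an error."""
    volume = load_volume(volume_path)
    if mask_path is None:
        return volume, None
    mask = load_mask(mask_path)
    if mask.labels.shape != volume.intensities.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match volume shape "
            f"{volume.intensities.shape} for {volume_path}"
        )
    if not np.allclose(mask.spacing_mm, volume.spacing_mm, rtol=1e-4):
        raise ValueError("mask spacing does not match volume spacing")
    mask.case_id = volume.case_id
    return volume, mask


# -- manifest ---------------------------------------------------------------

_MANIFEST_FIELDS = ["case_id", "role", "volume_path", "mask_path", "dz", "dy", "dx"]


def write_manifest(manifest: CaseManifest, path, force: bool = False):
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"manifest {path} exists (use force=True to overwrite)")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_MANIFEST_FIELDS)
        for e in manifest.entries:
            dz, dy, dx = e.spacing_mm
            writer.writerow([e.case_id, e.role, e.volume_path, e.mask_path, dz, dy, dx])


def read_manifest(path) -> CaseManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.append(ManifestEntry(
                case_id=row["case_id"],
                role=row["role"],
                volume_path=row["volume_path"],
                mask_path=row["mask_path"] or "",
                spacing_mm=(float(row["dz"]), float(row["dy"]), float(row["dx"])),
            ))
    return CaseManifest(entries)


def split_manifest(manifest: CaseManifest, fractions, seed: int) -> CaseManifest:
    """Seeded random train/test assignment of the labeled cases.

    ``fractions`` is (train, test); the remainder of the labeled cases (and
    every already-unlabeled case) becomes unlabeled. Rounds to nearest, so
    e.g. 207 labeled cases at fractions (138/207, 69/207) give exactly
    138 train and 69 test.
    """
    f_train, f_test = fractions
    if f_train < 0 or f_test < 0 or f_train + f_test > 1 + 1e-9:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    labeled = [e for e in manifest.entries if e.mask_path]
    unlabeled = [e for e in manifest.entries if not e.mask_path]
    n = len(labeled)
    n_train = int(round(f_train * n))
    n_test = min(int(round(f_test * n)), n - n_train)
    if f_test > 0 and n_test == 0:
        raise ValueError("not enough labeled cases for a non-empty test set")
    order = np.random.default_rng(seed).permutation(n)
    new_entries = {e.case_id: replace(e) for e in manifest.entries}
    for rank, idx in enumerate(order):
        e = labeled[idx]
        if rank < n_train:
            role = "train"
        elif rank < n_train + n_test:
            role = "test"
        else:
            role = "unlabeled"
        new_entries[e.case_id].role = role
    for e in unlabeled:
        new_entries[e.case_id].role = "unlabeled"
    out = [new_entries[e.case_id] for e in manifest.entries]
    # manifest invariant: unlabeled entries carry no mask path
    for e in out:
        if e.role == "unlabeled":
            e.mask_path = ""
    return CaseManifest(out)
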
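"""Voxel-wise segmentation metrics: DSC, recall, precision, H95, volume.

Formulas: DSC = 2 TP / (2 TP + FP + FN); recall = TP / (TP + FN);
precision = TP / (TP + FP). Specificity is deliberately not computed: with
vastly more background than lesion voxels it saturates near 1 and carries
no information. Empty-mask conventions (configurable in the report): when
prediction and ground truth are both empty, DSC = 1.0; an empty
denominator gives recall/precision = 1.0 (nothing claimed, nothing
missed). The 95th-percentile Hausdorff distance is computed over boundary
voxel centres in physical mm as the max of the two directed 95th
percentiles, with linear interpolation between order statistics; it is
undefined (and excluded from aggregates) when either mask is empty.

All metrics are evaluated per case on the native voxel grid and aggregated
as unweighted means over cases.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import CaseManifest, LesionMask, load_case
from .model import EnsembleModel, binarize, predict_volume
from .preprocess import normalize_volume

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "dsc",
    "recall",
    "precision",
    "hausdorff95",
    "lesion_volume_ml",
    "evaluate_model",
    "corrected_processing_time",
]


@dataclass
class ConfusionCounts:
    """Voxel-wise joint counts; tp+fp+fn+tn equals the voxels considered."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _as_binary(mask) -> np.ndarray:
    arr = mask.labels if isinstance(mask, LesionMask) else np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask must be binary")
    return arr.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    p = _as_binary(pred)
    g = _as_binary(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(counts: ConfusionCounts) -> float:
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0  # both masks empty: perfect agreement by convention
    return 2 * counts.tp / denom


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    if denom == 0:
        return 1.0
    return counts.tp / denom


def _boundary_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates (mm) of boundary voxel centres (6-connected erosion)."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    boundary = mask & ~eroded
    pts = np.argwhere(boundary).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def hausdorff95(pred, gt, spacing_mm=None):
    """95th-percentile symmetric Hausdorff distance in mm, or None if undefined.

    Directed distances are nearest-boundary-point distances; H95 is the max
    of the two directed 95th percentiles (linear-interpolated). Returns
    None when either mask is empty.
    """
    if isinstance(pred, LesionMask) and spacing_mm is None:
        if tuple(pred.spacing_mm) != tuple(gt.spacing_mm):
            raise ValueError("spacing mismatch between masks")
        spacing_mm = pred.spacing_mm
    if spacing_mm is None:
        raise ValueError("spacing_mm required")
    p = _as_binary(pred)
    g = _as_binary(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() or not g.any():
        return None
    bp = _boundary_points_mm(p, spacing_mm)
    bg = _boundary_points_mm(g, spacing_mm)
    d_pg, _ = cKDTree(bg).query(bp, k=1)
    d_gp, _ = cKDTree(bp).query(bg, k=1)
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


def lesion_volume_ml(mask: LesionMask) -> float:
    """Lesion volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    dz, dy, dx = mask.spacing_mm
    return float(np.count_nonzero(mask.labels)) * dz * dy * dx / 1000.0


@dataclass
class MetricsReport:
    """Per-case metric rows plus unweighted aggregate means."""

    per_case: list = field(default_factory=list)  # dict rows

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_case)

    @property
    def aggregate(self) -> dict:
        df = self.to_dataframe()
        if df.empty:
            return {}
        agg = {
            "dsc": float(df["dsc"].mean()),
            "recall": float(df["recall"].mean()),
            "precision": float(df["precision"].mean()),
        }
        h95 = df["h95_mm"].dropna()
        agg["h95_mm"] = float(h95.mean()) if len(h95) else float("nan")
        agg["gt_volume_ml"] = float(df["gt_volume_ml"].mean())
        agg["pred_volume_ml"] = float(df["pred_volume_ml"].mean())
        return agg

    def to_csv(self, path):
        df = self.to_dataframe()
        agg = self.aggregate
        if agg:
            agg_row = {"case_id": "AGGREGATE_MEAN", **{k: v for k, v in agg.items()}}
            df = pd.concat([df, pd.DataFrame([agg_row])], ignore_index=True)
        df.to_csv(path, index=False)


def case_metrics(pred_mask: LesionMask, gt_mask: LesionMask) -> dict:
    counts = confusion_counts(pred_mask, gt_mask)
    return {
        "case_id": gt_mask.case_id or pred_mask.case_id,
        "dsc": dsc(counts),
        "recall": recall(counts),
        "precision": precision(counts),
        "h95_mm": hausdorff95(pred_mask, gt_mask),
        "gt_volume_ml": lesion_volume_ml(gt_mask),
        "pred_volume_ml": lesion_volume_ml(pred_mask),
    }


def evaluate_model(model: EnsembleModel, manifest: CaseManifest, role: str = "test") -> MetricsReport:
    """Preprocess -> predict -> restore -> binarize -> score each labeled case."""
    cases = manifest.by_role(role)
    if not cases:
        raise ValueError(f"manifest has no {role} cases")
    report = MetricsReport()
    for entry in cases:
        volume, gt = load_case(entry.volume_path, entry.mask_path)
        probs = predict_volume(model, normalize_volume(volume))
        pred = LesionMask(binarize(probs, model.threshold), volume.spacing_mm, volume.case_id)
        report.per_case.append(case_metrics(pred, gt))
    from .nn import trim_memory
    trim_memory()
    return report


def corrected_processing_time(
    measured_seconds: float,
    measured_slices: int,
    measured_cpu_ghz: float,
    reference_slices: int = 192,
    reference_cpu_ghz: float = 3.5,
) -> float:
    """Normalize a measured per-case runtime to a reference workload, in minutes.

    corrected = measured_minutes x (reference_slices / measured_slices)
    x (measured_cpu_ghz / reference_cpu_ghz): scales to a reference slice
    count assuming time proportional to slices, and to a reference CPU
    clock assuming time inversely proportional to frequency.
    """
    args = (measured_seconds, measured_slices, measured_cpu_ghz, reference_slices, reference_cpu_ghz)
    if any(a <= 0 for a in args):
        raise ValueError("all arguments must be positive")
    return (measured_seconds / 60.0) * (reference_slices / measured_slices) * (measured_cpu_ghz / reference_cpu_ghz)


def timed_prediction_seconds(model: EnsembleModel, volume) -> float:
    """Single-case wall-clock segmentation time (informational only)."""
    t0 = _time.perf_counter()
    probs = predict_volume(model, normalize_volume(volume))
    binarize(probs, model.threshold)
    return _time.perf_counter() - t0
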
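"""Evaluation stack vs independent oracles; conventions and invariances."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from wmhseg.io import LesionMask
from wmhseg.metrics import (
    ConfusionCounts,
    confusion_counts,
    corrected_processing_time,
    case_metrics,
    dsc,
    hausdorff95,
    lesion_volume_ml,
    precision,
    recall,
)


# -- independent oracles ----------------------------------------------------


def loop_confusion(pred, gt):
    """Brute-force per-voxel loop (independent of the vectorised path)."""
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel().tolist(), gt.ravel().tolist()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_h95(pred, gt, spacing):
    """All-pairs O(N^2) 95th-percentile Hausdorff on boundary voxel centres."""
    struct = ndimage.generate_binary_structure(3, 1)

    def boundary(m):
        return np.argwhere(m & ~ndimage.binary_erosion(m, structure=struct)) * np.asarray(spacing)

    bp, bg = boundary(pred.astype(bool)), boundary(gt.astype(bool))
    d = cdist(bp, bg)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


# -- confusion counts / ratios ---------------------------------------------


def test_confusion_counts_match_loop_oracle(rng):
    for _ in range(20):
        pred = rng.random((8, 8, 8)) > 0.6
        gt = rng.random((8, 8, 8)) > 0.6
        c = confusion_counts(pred.astype(np.uint8), gt.astype(np.uint8))
        assert (c.tp, c.fp, c.fn, c.tn) == loop_confusion(pred, gt)
        assert c.tp + c.fp + c.fn + c.tn == pred.size


def test_confusion_edge_cases():
    ones = np.ones((2, 2, 2), dtype=np.uint8)
    zeros = np.zeros_like(ones)
    c = confusion_counts(ones, ones)
    assert (c.tp, c.fp, c.fn, c.tn) == (8, 0, 0, 0)
    c = confusion_counts(ones, zeros)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 8, 0, 0)
    with pytest.raises(ValueError):
        confusion_counts(ones, np.zeros((2, 2, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        confusion_counts(np.full((2, 2, 2), 2, dtype=np.uint8), zeros)


@pytest.mark.parametrize("counts,expected", [
    (ConfusionCounts(2, 1, 1, 10), 4 / 6),
    (ConfusionCounts(5, 0, 0, 10), 1.0),
    (ConfusionCounts(0, 3, 2, 10), 0.0),
    (ConfusionCounts(0, 0, 0, 10), 1.0),  # both empty: agreement by convention
])
def test_dsc_formula_and_conventions(counts, expected):
    assert dsc(counts) == pytest.approx(expected)


def test_recall_precision_formulas_and_conventions():
    c = ConfusionCounts(3, 1, 1, 10)
    assert recall(c) == pytest.approx(0.75)
    assert precision(c) == pytest.approx(0.75)
    empty = ConfusionCounts(0, 0, 0, 8)
    assert recall(empty) == 1.0 and precision(empty) == 1.0


def test_dsc_symmetric_and_monotone(rng):
    pred = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
    gt = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
    assert dsc(confusion_counts(pred, gt)) == pytest.approx(dsc(confusion_counts(gt, pred)))
    # converting one FN voxel into a TP never decreases DSC or recall
    fn_voxels = np.argwhere(gt.astype(bool) & ~pred.astype(bool))
    if len(fn_voxels):
        better = pred.copy()
        better[tuple(fn_voxels[0])] = 1
        assert dsc(confusion_counts(better, gt)) >= dsc(confusion_counts(pred, gt))
        assert recall(confusion_counts(better, gt)) >= recall(confusion_counts(pred, gt))


# -- Hausdorff --------------------------------------------------------------


def test_h95_identical_masks_zero(rng):
    m = (rng.random((4, 10, 10)) > 0.7).astype(np.uint8)
    m[0, 0, 0] = 1
    assert hausdorff95(m, m, (5.0, 1.0, 1.0)) == 0.0


def test_h95_single_voxel_offset_in_plane():
    a = np.zeros((3, 8, 8), dtype=np.uint8)
    b = np.zeros_like(a)
    a[1, 4, 4] = 1
    b[1, 4, 5] = 1
    assert hausdorff95(a, b, (5.0, 1.0, 1.0)) == pytest.approx(1.0)


def test_h95_matches_brute_force_oracle(rng):
    for _ in range(15):
        pred = np.zeros((5, 12, 12), dtype=np.uint8)
        gt = np.zeros_like(pred)
        for m in (pred, gt):
            n_blobs = rng.integers(1, 4)
            for _ in range(n_blobs):
                z, y, x = rng.integers(0, 5), rng.integers(2, 10), rng.integers(2, 10)
                m[z, y - 1:y + 2, x - 1:x + 2] = 1
        spacing = (float(rng.uniform(5, 6)), 1.0, 1.0)
        ours = hausdorff95(pred, gt, spacing)
        assert ours == pytest.approx(brute_h95(pred, gt, spacing), abs=1e-9)


def test_h95_undefined_when_either_empty():
    m = np.zeros((2, 4, 4), dtype=np.uint8)
    n = m.copy()
    n[0, 1, 1] = 1
    assert hausdorff95(m, n, (5, 1, 1)) is None
    assert hausdorff95(n, m, (5, 1, 1)) is None
    assert hausdorff95(m, m, (5, 1, 1)) is None


def test_h95_bounded_by_max_hausdorff_and_scales_with_spacing(rng):
    pred = (rng.random((4, 10, 10)) > 0.8).astype(np.uint8)
    gt = (rng.random((4, 10, 10)) > 0.8).astype(np.uint8)
    pred[0, 0, 0] = gt[1, 5, 5] = 1
    spacing = (5.0, 1.0, 1.0)
    h95 = hausdorff95(pred, gt, spacing)

    struct = ndimage.generate_binary_structure(3, 1)

    def boundary(m):
        return np.argwhere(m.astype(bool) & ~ndimage.binary_erosion(m.astype(bool), structure=struct)) * np.asarray(spacing)

    d = cdist(boundary(pred), boundary(gt))
    h100 = max(d.min(axis=1).max(), d.min(axis=0).max())
    assert h95 <= h100 + 1e-9
    doubled = hausdorff95(pred, gt, (10.0, 2.0, 2.0))
    assert doubled == pytest.approx(2 * h95)


# -- volume -----------------------------------------------------------------


@pytest.mark.parametrize("n_vox,spacing,expected", [
    (1000, (1.0, 1.0, 1.0), 1.0),
    (0, (5.0, 1.0, 1.0), 0.0),
    (100, (5.0, 0.5, 0.5), 0.125),
])
def test_lesion_volume_ml(n_vox, spacing, expected):
    labels = np.zeros(4096, dtype=np.uint8)
    labels[:n_vox] = 1
    mask = LesionMask(labels.reshape(16, 16, 16), spacing, "c")
    assert lesion_volume_ml(mask) == pytest.approx(expected)


# -- per-case metrics and aggregation ---------------------------------------


def test_case_metrics_perfect_and_allbackground(rng):
    gt_arr = np.zeros((3, 10, 10), dtype=np.uint8)
    gt_arr[1, 3:6, 3:6] = 1
    gt = LesionMask(gt_arr, (5.0, 1.0, 1.0), "c")
    perfect = case_metrics(gt, gt)
    assert perfect["dsc"] == 1.0 and perfect["h95_mm"] == 0.0
    empty = LesionMask(np.zeros_like(gt_arr), gt.spacing_mm, "c")
    miss = case_metrics(empty, gt)
    assert miss["dsc"] == 0.0 and miss["recall"] == 0.0
    assert miss["h95_mm"] is None
    assert miss["pred_volume_ml"] == 0.0


def test_aggregate_mean_matches_per_case_rows_and_ordering(rng):
    from wmhseg.metrics import MetricsReport
    rows = []
    for i in range(5):
        pred = (rng.random((3, 8, 8)) > 0.5).astype(np.uint8)
        gt = (rng.random((3, 8, 8)) > 0.5).astype(np.uint8)
        pm = LesionMask(pred, (5, 1, 1), f"c{i}")
        gm = LesionMask(gt, (5, 1, 1), f"c{i}")
        rows.append(case_metrics(pm, gm))
    report = MetricsReport(per_case=rows)
    shuffled = MetricsReport(per_case=list(reversed(rows)))
    assert report.aggregate["dsc"] == pytest.approx(np.mean([r["dsc"] for r in rows]))
    assert report.aggregate["dsc"] == pytest.approx(shuffled.aggregate["dsc"])
    assert report.aggregate["h95_mm"] == pytest.approx(shuffled.aggregate["h95_mm"])


# -- processing-time correction ---------------------------------------------


def test_corrected_time_reference_identity_and_proportionality():
    assert corrected_processing_time(120.0, 192, 3.5) == pytest.approx(2.0)
    half = corrected_processing_time(60.0, 44, 2.3)
    full = corrected_processing_time(60.0, 22, 2.3)
    assert half == pytest.approx(full / 2)
    with pytest.raises(ValueError):
        corrected_processing_time(-1.0, 22, 2.3)
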
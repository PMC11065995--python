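"""Phantom generator: determinism, guideline compliance, burden realism."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest
from scipy import stats

from wmhseg.io import read_manifest
from wmhseg.metrics import lesion_volume_ml
from wmhseg.phantom import PhantomConfig, burden_histogram, generate_case, generate_dataset

from conftest import tiny_phantom_config


def _clean_wm(case):
    """White matter excluding lesions and distractors (for intensity means)."""
    wm = case.wm_mask.labels.astype(bool)
    return wm & ~case.wmh_mask.labels.astype(bool) & ~case.lacune_mask.labels.astype(bool) \
        & ~case.epvs_mask.labels.astype(bool)


def test_same_seed_same_case_bit_identical():
    config = tiny_phantom_config(seed=5)
    a = generate_case(config, 2)
    b = generate_case(config, 2)
    np.testing.assert_array_equal(a.volume.intensities, b.volume.intensities)
    np.testing.assert_array_equal(a.wmh_mask.labels, b.wmh_mask.labels)
    assert a.volume.spacing_mm == b.volume.spacing_mm


def test_different_seeds_differ():
    a = generate_case(tiny_phantom_config(seed=5), 0)
    b = generate_case(tiny_phantom_config(seed=6), 0)
    assert not np.array_equal(a.volume.intensities, b.volume.intensities)


def test_case_independence_of_generation_order():
    """Case k is identical whether or not other cases were generated first."""
    config = tiny_phantom_config(seed=9, n_cases=4)
    direct = generate_case(config, 3)
    for i in range(3):
        generate_case(config, i)
    after = generate_case(config, 3)
    np.testing.assert_array_equal(direct.volume.intensities, after.volume.intensities)


def test_near_zero_burden_gives_empty_mask():
    config = tiny_phantom_config()
    config = PhantomConfig(**{**config.__dict__, "burden_lognormal": (-20.0, 0.01),
                              "distractor_rates": (0.0, 0.0), "ambiguous_speck_rate": 0.0})
    case = generate_case(config, 0)
    assert case.wmh_mask.labels.sum() == 0
    assert lesion_volume_ml(case.wmh_mask) == 0.0


def test_zero_distractor_rates_give_empty_distractors():
    config = PhantomConfig(**{**tiny_phantom_config().__dict__, "distractor_rates": (0.0, 0.0)})
    for i in range(3):
        case = generate_case(config, i)
        assert case.lacune_mask.labels.sum() == 0
        assert case.epvs_mask.labels.sum() == 0


def test_rejects_unresolvable_slice_shape():
    with pytest.raises(ValueError, match="32"):
        PhantomConfig(slice_shape=(16, 16))


def test_case_index_bounds():
    config = tiny_phantom_config(n_cases=2)
    with pytest.raises(ValueError):
        generate_case(config, 2)


def test_guideline_masks_and_intensity_ordering():
    """Ground truth avoids distractors; WMH > WM > EPVS; lacune centre < rim."""
    config = PhantomConfig(seed=3, n_cases=20, slice_shape=(64, 64), n_slices=6,
                           spacing_mm=(5.5, 3.4, 3.4), distractor_rates=(1.5, 3.0))
    saw_lacune = saw_epvs = 0
    for i in range(config.n_cases):
        case = generate_case(config, i)
        wmh = case.wmh_mask.labels.astype(bool)
        lac = case.lacune_mask.labels.astype(bool)
        epvs = case.epvs_mask.labels.astype(bool)
        assert not (wmh & lac).any()
        assert not (wmh & epvs).any()
        assert not (wmh & ~case.wm_mask.labels.astype(bool)).any()
        img = case.volume.intensities
        wm_mean = img[_clean_wm(case)].mean()
        if wmh.any():
            assert img[wmh].mean() > wm_mean
        if epvs.any():
            saw_epvs += 1
            assert img[epvs].mean() < wm_mean
        if lac.any():
            saw_lacune += 1
    assert saw_epvs >= 5  # distractors actually exercised
    assert saw_lacune >= 3


def test_periventricular_lesions_touch_ventricles_deep_ones_do_not():
    from scipy import ndimage
    config = PhantomConfig(seed=11, n_cases=6, slice_shape=(96, 96), n_slices=8,
                           spacing_mm=(5.5, 2.4, 2.4), pvh_fraction=1.0,
                           distractor_rates=(0, 0), ambiguous_speck_rate=0.0)
    deep_config = PhantomConfig(**{**config.__dict__, "pvh_fraction": 0.0})
    for i in range(3):
        pv_case = generate_case(config, i)
        if pv_case.wmh_mask.labels.any():
            vent_dil = np.stack([ndimage.binary_dilation(v, iterations=2)
                                 for v in pv_case.ventricle_mask.labels])
            assert (pv_case.wmh_mask.labels.astype(bool) & vent_dil.astype(bool)).any()
        deep_case = generate_case(deep_config, i)
        if deep_case.wmh_mask.labels.any():
            vent_dil = np.stack([ndimage.binary_dilation(v, iterations=1)
                                 for v in deep_case.ventricle_mask.labels])
            assert not (deep_case.wmh_mask.labels.astype(bool) & vent_dil.astype(bool)).any()


def test_slice_thickness_sampled_in_range():
    config = tiny_phantom_config(n_cases=8)
    thicknesses = [generate_case(config, i).volume.spacing_mm[0] for i in range(8)]
    assert all(5.0 <= t <= 6.0 for t in thicknesses)
    assert len(set(thicknesses)) > 1


def test_burden_distribution_right_skewed_small_sample():
    config = PhantomConfig(seed=21, n_cases=60, slice_shape=(64, 64), n_slices=6,
                           spacing_mm=(5.5, 3.4, 3.4))
    volumes = [lesion_volume_ml(generate_case(config, i).wmh_mask) for i in range(60)]
    assert stats.skew(volumes) > 0
    assert np.median(volumes) < np.mean(volumes)


def test_generate_dataset_split_and_roles(tmp_path):
    config = tiny_phantom_config(n_cases=10)
    manifest = generate_dataset(config, tmp_path / "d", split=(0.6, 0.2, 0.2))
    assert len(manifest.by_role("train")) == 6
    assert len(manifest.by_role("test")) == 2
    assert len(manifest.by_role("unlabeled")) == 2
    for entry in manifest.by_role("unlabeled"):
        assert entry.mask_path == ""
    for entry in manifest.by_role("train"):
        assert entry.mask_path
    with pytest.raises(FileExistsError):
        generate_dataset(config, tmp_path / "d", split=(0.6, 0.2, 0.2))


def test_regenerated_dataset_is_byte_identical(tmp_path):
    import gzip
    config = tiny_phantom_config(n_cases=3)
    m1 = generate_dataset(config, tmp_path / "a", split=(0.7, 0.3, 0.0))
    m2 = generate_dataset(config, tmp_path / "b", split=(0.7, 0.3, 0.0))

    def digest(path):
        # compare decompressed payload (gzip headers embed mtime)
        with gzip.open(path, "rb") as fh:
            return hashlib.sha256(fh.read()).hexdigest()

    for e1, e2 in zip(m1.entries, m2.entries):
        assert digest(e1.volume_path) == digest(e2.volume_path)
        if e1.mask_path:
            assert digest(e1.mask_path) == digest(e2.mask_path)


def test_burden_histogram_binning(tmp_path, tiny_dataset):
    config, manifest = tiny_dataset
    labeled = [e for e in manifest.entries if e.mask_path]
    from wmhseg.io import CaseManifest
    sub = CaseManifest(labeled)
    edges, counts = burden_histogram(sub, bin_width_ml=10.0)
    assert counts.sum() == len(labeled)
    total = sum(lesion_volume_ml(__import__("wmhseg.io", fromlist=["load_mask"]).load_mask(e.mask_path))
                for e in labeled)
    assert total > 0

    empty_edges, empty_counts = burden_histogram(CaseManifest([]))
    assert empty_counts.sum() == 0


def test_burden_histogram_requires_masks(tiny_dataset):
    _, manifest = tiny_dataset
    with pytest.raises(ValueError, match="mask"):
        burden_histogram(manifest)
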
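"""Synthetic FLAIR phantom generator with WMH ground truth and distractors.

Generates seeded, fully synthetic 3D "FLAIR-like" volumes so the whole
segmentation pipeline can be trained and evaluated without clinical data.
Each case contains:

* a parametric 2.5D brain: an elliptical brain outline per slice (an
  ellipsoid cap along the slice axis), a bright cortical band, darker
  white matter, and paired dark lateral ventricles with a thin bright
  septum band between them;
* WMH lesions — the brightest tissue class — split between a
  periventricular component (confluent caps hugging the ventricle margin)
  and deep subcortical punctate lesions, with per-case total volume drawn
  from a heavy-tailed lognormal so the cohort histogram is right-skewed;
* distractor lesions excluded from the ground truth, following clinical
  annotation guidelines: lacunar infarcts (hyperintense rim around a
  hypointense centre) and enlarged perivascular spaces (at or below
  white-matter intensity), plus occasional single-slice "ambiguous" bright
  specks that are deliberately left unlabeled;
* per-scanner contrast variation (brightness offset + gain), additive
  noise, and slice thickness drawn from 5-6 mm.

Determinism: each case uses an independent random stream derived from
(seed, case_index) via numpy's SeedSequence, so cases are order-insensitive
and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    CaseManifest,
    FlairVolume,
    LesionMask,
    ManifestEntry,
    save_mask,
    save_volume,
    write_manifest,
)

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_dataset", "burden_histogram"]

# tissue intensity palette (arbitrary pre-scanner units in [0, 1])
_BACKGROUND = 0.02
_CSF = 0.08
_WM = 0.45
_CORTEX = 0.58
_SEPTUM = 0.66
_WMH = 0.86
_LACUNE_RIM = 0.62
_LACUNE_CENTER = 0.14
_EPVS = 0.26
_SPECK = 0.72


@dataclass
class PhantomConfig:
    """Generation parameters; identical config + seed give bit-identical output.

    ``burden_lognormal`` is (mu, sigma) of the per-case total WMH volume in
    mL; the default is moment-matched to a cohort mean of 18.11 mL with
    standard deviation 22.07 mL. ``spacing_mm`` is (dz, dy, dx); dz is
    resampled per case from ``dz_range_mm`` (5-6 mm thick slices) unless
    that is None. ``contrast_profiles`` are (brightness offset, gain) pairs
    emulating scanners; cases cycle through them. ``distractor_rates`` are
    expected (lacunar infarct, EPVS) counts per case.
    """

    seed: int = 0
    n_cases: int = 30
    slice_shape: tuple = (128, 128)
    n_slices: int = 10
    spacing_mm: tuple = (5.5, 1.8, 1.8)
    dz_range_mm: tuple | None = (5.0, 6.0)
    burden_lognormal: tuple = (2.4407, 0.9540)
    pvh_fraction: float = 0.6
    distractor_rates: tuple = (0.3, 2.0)
    contrast_profiles: tuple = ((0.0, 1.0), (0.05, 0.9), (-0.03, 1.15))
    noise_sigma: float = 0.025
    pv_rim_mm: float = 7.0
    ambiguous_speck_rate: float = 1.0
    intensity_scale: float = 600.0

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if min(self.slice_shape) < 32:
            raise ValueError("slice_shape must be at least 32x32 (anatomy templates unresolvable)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if not (0.0 <= self.pvh_fraction <= 1.0):
            raise ValueError("pvh_fraction must lie in [0, 1]")
        if any(r < 0 for r in self.distractor_rates):
            raise ValueError("distractor rates must be non-negative")
        if self.noise_sigma < 0 or self.ambiguous_speck_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_slices < 1:
            raise ValueError("n_slices must be at least 1")


@dataclass
class PhantomCase:
    """One generated case: volume, ground truth, distractors, anatomy."""

    volume: FlairVolume
    wmh_mask: LesionMask          # ground truth
    lacune_mask: LesionMask       # distractor, excluded from ground truth
    epvs_mask: LesionMask         # distractor, excluded from ground truth
    ventricle_mask: LesionMask    # anatomy
    wm_mask: LesionMask           # simulated cerebral white-matter template

    def __post_init__(self):
        shape = self.volume.intensities.shape
        for m in (self.wmh_mask, self.lacune_mask, self.epvs_mask, self.ventricle_mask, self.wm_mask):
            if m.labels.shape != shape:
                raise ValueError("all masks must share the volume's shape")
        if (self.wmh_mask.labels & self.lacune_mask.labels).any():
            raise ValueError("WMH ground truth overlaps a lacune")
        if (self.wmh_mask.labels & self.epvs_mask.labels).any():
            raise ValueError("WMH ground truth overlaps an EPVS")
        if (self.wmh_mask.labels & ~self.wm_mask.labels.astype(bool)).any():
            raise ValueError("WMH ground truth leaves the white-matter template")


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, case_index)))


def _anatomy(rng, shape, n_slices, spacing):
    """Brain/cortex/white-matter/ventricle/septum masks for one case."""
    H, W = shape
    S = n_slices
    yy, xx = np.mgrid[0:H, 0:W]
    yc, xc = H / 2 + rng.uniform(-2, 2), W / 2 + rng.uniform(-2, 2)
    ay, ax = H * rng.uniform(0.40, 0.44), W * rng.uniform(0.34, 0.38)

    brain = np.zeros((S, H, W), dtype=bool)
    vent = np.zeros((S, H, W), dtype=bool)
    septum = np.zeros((S, H, W), dtype=bool)
    zc = (S - 1) / 2
    for z in range(S):
        f = np.sqrt(max(0.05, 1.0 - ((z - zc) / (S / 2 + 0.5)) ** 2))
        brain[z] = ((yy - yc) / (ay * f)) ** 2 + ((xx - xc) / (ax * f)) ** 2 <= 1.0
        if f > 0.6:
            # paired lateral ventricles: elongated ellipses flanking midline
            for side in (-1, 1):
                vy, vx = yc - 0.05 * H, xc + side * 0.09 * W
                vay, vax = 0.16 * H * f, 0.035 * W * (0.6 + 0.4 * f)
                vent[z] |= ((yy - vy) / vay) ** 2 + ((xx - vx) / vax) ** 2 <= 1.0
            # septum pellucidum: thin bright band between the ventricles
            band = (np.abs(xx - xc) <= max(1.0, 0.012 * W)) & (np.abs(yy - (yc - 0.05 * H)) <= 0.10 * H)
            septum[z] = band & brain[z] & ~vent[z]
    vent &= brain

    interior = np.stack([ndimage.binary_erosion(b, iterations=max(2, int(0.03 * min(H, W)))) for b in brain])
    cortex = brain & ~interior
    vent_dil = np.stack([ndimage.binary_dilation(v, iterations=1) for v in vent])
    wm = interior & ~vent_dil & ~septum
    return brain, cortex, wm, vent, septum


def _pv_distance(vent, wm, spacing):
    """In-plane distance (mm) from each voxel to the nearest ventricle voxel."""
    _, dy, dx = spacing
    S = vent.shape[0]
    dist = np.full(vent.shape, np.inf)
    for z in range(S):
        if vent[z].any():
            dist[z] = ndimage.distance_transform_edt(~vent[z], sampling=(dy, dx))
    return dist


def _top_k(field, region, k):
    """Mask of the k largest field values inside region (exactly k if possible)."""
    out = np.zeros(field.shape, dtype=bool)
    k = min(int(k), int(region.sum()))
    if k <= 0:
        return out
    vals = np.where(region, field, -np.inf).ravel()
    idx = np.argpartition(vals, -k)[-k:]
    out.ravel()[idx] = True
    return out


def _smooth_field(rng, shape, sigma):
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)


def generate_case(config: PhantomConfig, case_index: int) -> PhantomCase:
    """Generate one phantom case deterministically from (config.seed, case_index)."""
    if not (0 <= case_index < config.n_cases):
        raise ValueError(f"case_index {case_index} outside [0, {config.n_cases})")
    rng = _case_rng(config.seed, case_index)
    H, W = config.slice_shape
    S = config.n_slices
    dz, dy, dx = config.spacing_mm
    if config.dz_range_mm is not None:
        dz = float(rng.uniform(*config.dz_range_mm))
    spacing = (dz, dy, dx)
    voxel_ml = dz * dy * dx / 1000.0

    brain, cortex, wm, vent, septum = _anatomy(rng, (H, W), S, spacing)
    dist = _pv_distance(vent, wm, spacing)

    # -- distractors first: lesions are placed away from them ------------
    lacune = np.zeros((S, H, W), dtype=bool)
    lacune_center = np.zeros((S, H, W), dtype=bool)
    n_lac = rng.poisson(config.distractor_rates[0])
    deep_region = wm & (dist > config.pv_rim_mm)
    candidates = np.argwhere(deep_region if deep_region.any() else wm)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n_lac):
        if len(candidates) == 0:
            break
        z0, y0, x0 = candidates[rng.integers(len(candidates))]
        r = rng.uniform(2.0, 3.5)
        disk = ((yy - y0) ** 2 + (xx - x0) ** 2) <= r ** 2
        core = ((yy - y0) ** 2 + (xx - x0) ** 2) <= max(1.0, r / 2) ** 2
        for z in range(max(0, z0), min(S, z0 + (2 if rng.random() < 0.3 else 1))):
            lacune[z] |= disk & wm[z]
            lacune_center[z] |= core & wm[z]

    epvs = np.zeros((S, H, W), dtype=bool)
    n_epvs = rng.poisson(config.distractor_rates[1])
    for _ in range(n_epvs):
        if len(candidates) == 0:
            break
        z0, y0, x0 = candidates[rng.integers(len(candidates))]
        blob = ((yy - y0) ** 2 + (xx - x0) ** 2) <= rng.uniform(1.0, 1.8) ** 2
        epvs[z0] |= blob & wm[z0]
    epvs &= ~lacune

    # -- WMH ground truth: exact per-case volume from the lognormal burden
    target_ml = float(rng.lognormal(*config.burden_lognormal))
    target_vox = int(round(target_ml / voxel_ml))
    distract_keepout = np.stack([ndimage.binary_dilation(m, iterations=2) for m in (lacune | epvs)])
    allowed = wm & ~distract_keepout
    pv_shell = allowed & (dist <= config.pv_rim_mm)
    deep = allowed & (dist > config.pv_rim_mm)

    k_pv = int(round(config.pvh_fraction * target_vox))
    k_deep = target_vox - k_pv
    # smooth 3D fields -> blobby, multi-slice lesions; the periventricular
    # field is biased toward the ventricle margin so caps hug the ventricles
    f_pv = _smooth_field(rng, (S, H, W), sigma=(0.8, 2.5, 2.5))
    with np.errstate(invalid="ignore"):
        prox = np.where(np.isfinite(dist), np.clip(1.0 - dist / config.pv_rim_mm, 0, 1), 0.0)
    f_pv = f_pv + 2.0 * prox
    f_deep = _smooth_field(rng, (S, H, W), sigma=(0.7, 1.4, 1.4))
    wmh = _top_k(f_pv, pv_shell, k_pv) | _top_k(f_deep, deep, k_deep)

    # -- ambiguous single-slice bright specks, deliberately unlabeled ----
    speck = np.zeros((S, H, W), dtype=bool)
    for _ in range(rng.poisson(config.ambiguous_speck_rate)):
        cand = np.argwhere(allowed & ~wmh)
        if len(cand) == 0:
            break
        z0, y0, x0 = cand[rng.integers(len(cand))]
        blob = ((yy - y0) ** 2 + (xx - x0) ** 2) <= rng.uniform(0.8, 1.4) ** 2
        speck[z0] |= blob & allowed[z0] & ~wmh[z0]

    # -- compose intensities ---------------------------------------------
    img = np.full((S, H, W), _BACKGROUND, dtype=np.float64)
    img[brain] = _CORTEX
    img[wm] = _WM
    img[cortex] = _CORTEX
    img[vent] = _CSF
    img[septum] = _SEPTUM
    img[epvs] = _EPVS
    img[wmh] = _WMH
    img[speck] = _SPECK
    img[lacune] = _LACUNE_RIM
    img[lacune_center] = _LACUNE_CENTER
    # mild in-plane smoothing emulates partial-volume blur
    img = np.stack([ndimage.gaussian_filter(s, sigma=0.5) for s in img])

    offset, gain = config.contrast_profiles[case_index % len(config.contrast_profiles)]
    img = offset + gain * img
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma * gain, size=img.shape)
    img = np.clip(img, 0.0, None) * config.intensity_scale

    case_id = f"case{case_index:04d}"
    volume = FlairVolume(img.astype(np.float32), spacing, case_id)

    def _mask(arr):
        return LesionMask(arr.astype(np.uint8), spacing, case_id)

    return PhantomCase(
        volume=volume,
        wmh_mask=_mask(wmh),
        lacune_mask=_mask(lacune),
        epvs_mask=_mask(epvs),
        ventricle_mask=_mask(vent),
        wm_mask=_mask(wm),
    )


def generate_dataset(
    config: PhantomConfig,
    out_dir,
    split=(0.6, 0.2, 0.2),
    force: bool = False,
) -> CaseManifest:
    """Write phantom volumes + ground-truth masks and return the manifest.

    Roles are assigned deterministically by the configured (train, test,
    unlabeled) proportions; unlabeled cases get no mask file, emulating an
    unannotated pool. Refuses to overwrite an existing manifest unless
    ``force`` is set.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.tsv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    if abs(sum(split) - 1.0) > 1e-9 or any(s < 0 for s in split):
        raise ValueError("split proportions must be non-negative and sum to 1")
    n = config.n_cases
    n_train = int(round(split[0] * n))
    n_test = min(int(round(split[1] * n)), n - n_train)
    roles = ["train"] * n_train + ["test"] * n_test + ["unlabeled"] * (n - n_train - n_test)

    entries = []
    for i in range(n):
        case = generate_case(config, i)
        role = roles[i]
        vol_path = out_dir / f"{case.volume.case_id}_flair.nii.gz"
        save_volume(case.volume, vol_path)
        mask_path = ""
        if role != "unlabeled":
            mask_path = str(out_dir / f"{case.volume.case_id}_wmh.nii.gz")
            save_mask(case.wmh_mask, mask_path)
        entries.append(ManifestEntry(
            case_id=case.volume.case_id,
            role=role,
            volume_path=str(vol_path),
            mask_path=mask_path,
            spacing_mm=case.volume.spacing_mm,
        ))
    manifest = CaseManifest(entries)
    write_manifest(manifest, manifest_path, force=force)
    return manifest


def burden_histogram(manifest: CaseManifest, bin_width_ml: float = 10.0, n_bins: int = 12):
    """Per-case WMH volume histogram (mL bins -> case counts).

    Returns (bin_edges, counts); the last bin absorbs volumes past the
    range. Requires every manifest case to reference a ground-truth mask.
    """
    from .io import load_mask
    from .metrics import lesion_volume_ml

    volumes = []
    for e in manifest.entries:
        if not e.mask_path:
            raise ValueError(f"case {e.case_id} has no ground-truth mask")
        if not Path(e.mask_path).exists():
            raise FileNotFoundError(e.mask_path)
        volumes.append(lesion_volume_ml(load_mask(e.mask_path)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_ml
    if volumes:
        clipped = np.minimum(volumes, edges[-1] - 1e-9)
        counts, _ = np.histogram(clipped, bins=edges)
    else:
        counts = np.zeros(n_bins, dtype=int)
    return edges, counts
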
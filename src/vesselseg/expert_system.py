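"""Feature-based expert system: rule-driven spine, lumen and thrombus segmentation.

The pipeline applies programmed image-processing rules — no learning:

1. **Pre-processing** — Gaussian smoothing with a physical (mm) sigma.
2. **Spine** — HU thresholding at a bone threshold, morphological closing to
   bridge inter-vertebral gaps, and restriction to 3D connected components
   whose centroid lies in the posterior half of the slice.
3. **Lumen** — a seed region is found on the mid-volume slice as the largest
   bright, roughly circular component inside a contrast HU window and
   anterior to the spine; the seed contour is refined by a morphological
   active contour without edges (Chan–Vese energy evolved by morphological
   operators), then propagated slice-to-slice in both directions, each new
   slice accepted while it overlaps the previous converged contour.
4. **Thrombus** — per slice, a morphological snake initialized from the
   dilated lumen evolves on a soft-tissue-windowed image (with the bright
   lumen in-painted to the local soft-tissue level); the converged region
   minus the lumen is the thrombus.

Everything here is deterministic; failure to find a lumen seed is a
structured status, not an exception, mirroring how the method degrades on
low-contrast scans.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk as disk_element
from skimage.segmentation import morphological_chan_vese

from .imaging_io import BinaryMask3D, CTVolume

# in-slice connectivity 8 (connectivity=2), 3D connectivity 26
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ExpertConfig:
    """Every tunable the rule pipeline needs, with defaults written out."""

    smoothing_sigma_mm: float = 1.0
    bone_threshold_hu: float = 200.0
    lumen_window_hu: tuple[float, float] = (150.0, 600.0)
    # seed search: fraction of the anterior-of-spine region searched, and
    # admissibility bounds for candidate regions
    seed_search_fraction: float = 1.0
    min_seed_area_mm2: float = 40.0
    max_seed_eccentricity: float = 0.85
    acwe_iterations: int = 25
    acwe_smoothing: int = 1
    propagation_overlap_min: float = 0.5
    # spine closing ball (physical) used to bridge inter-vertebral gaps
    spine_closing_mm: float = 2.5
    # thrombus snake
    thrombus_dilation_mm: float = 8.0
    thrombus_acwe_iterations: int = 40
    thrombus_acwe_smoothing: int = 2
    thrombus_window_hu: tuple[float, float] = (-100.0, 150.0)
    thrombus_min_contrast_hu: float = 3.0
    # pre-snake gate on the raw dilation annulus (selection-free): if the
    # ring around the lumen shows no mean HU elevation over the local
    # background, the slice carries no thrombus (~3 sigma of the smoothed
    # noise floor)
    thrombus_min_annulus_contrast_hu: float = 1.0
    # ring around the lumen in-painted together with it (partial-volume edge)
    thrombus_inpaint_margin_mm: float = 1.6
    # extra in-crop smoothing before the snake (thrombus contrast is small)
    thrombus_crop_smoothing_mm: float = 0.8
    # window applied before the lumen active contour (tames residual bone)
    lumen_clip_hu: tuple[float, float] = (-100.0, 500.0)

    def __post_init__(self) -> None:
        lo, hi = self.lumen_window_hu
        if not lo < hi:
            raise ValueError("lumen_window_hu must satisfy low < high")
        for name in ("acwe_iterations", "thrombus_acwe_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.propagation_overlap_min <= 1.0):
            raise ValueError("propagation_overlap_min must be in (0, 1]")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["lumen_window_hu"] = list(d["lumen_window_hu"])
        d["thrombus_window_hu"] = list(d["thrombus_window_hu"])
        d["lumen_clip_hu"] = list(d["lumen_clip_hu"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExpertConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("lumen_window_hu", "thrombus_window_hu", "lumen_clip_hu"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class LumenResult:
    """Lumen segmentation output with a structured status.

    status is ``"ok"`` or ``"lumen-not-found"``; seed_source records where
    the seed came from (``"expert-window"`` or ``"network"``).
    """

    mask: BinaryMask3D
    status: str
    seed_source: Optional[str] = None
    seed_slice: Optional[int] = None

    @property
    def found(self) -> bool:
        return self.status == "ok"


def preprocess(volume: CTVolume, cfg: ExpertConfig) -> CTVolume:
    """Gaussian smoothing with a physical sigma, converted per axis.

    Identity for ``smoothing_sigma_mm = 0``; HU range is preserved (Gaussian
    averaging cannot leave the input's convex hull of values).
    """
    if cfg.smoothing_sigma_mm == 0:
        return volume.copy()
    row_mm, col_mm, slice_mm = volume.spacing
    sigma = (cfg.smoothing_sigma_mm / slice_mm,
             cfg.smoothing_sigma_mm / row_mm,
             cfg.smoothing_sigma_mm / col_mm)
    smoothed = ndimage.gaussian_filter(volume.voxels.astype(np.float32), sigma=sigma)
    return CTVolume(smoothed, volume.spacing)


def _ellipsoid_element(radii_vox: tuple[float, float, float]) -> np.ndarray:
    rz, rr, rc = (max(int(round(r)), 0) for r in radii_vox)
    zz, yy, xx = np.mgrid[-rz:rz + 1, -rr:rr + 1, -rc:rc + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = ((zz / max(rz, 1e-9)) ** 2 + (yy / max(rr, 1e-9)) ** 2
             + (xx / max(rc, 1e-9)) ** 2)
    return q <= 1.0


def segment_spine(volume: CTVolume, cfg: ExpertConfig) -> BinaryMask3D:
    """Bone thresholding + closing + posterior connected-component filter."""
    vox = volume.voxels
    thresh = vox >= cfg.bone_threshold_hu
    if not thresh.any():
        warnings.warn("no voxel reaches the bone threshold; returning empty spine mask")
        return BinaryMask3D(np.zeros_like(vox, dtype=np.uint8), "spine", volume.spacing)

    row_mm, col_mm, slice_mm = volume.spacing
    radii = (cfg.spine_closing_mm / slice_mm,
             cfg.spine_closing_mm / row_mm,
             cfg.spine_closing_mm / col_mm)
    closed = ndimage.binary_closing(thresh, structure=_ellipsoid_element(radii))
    closed |= thresh  # closing never removes thresholded voxels

    labels, n = ndimage.label(closed, structure=_STRUCT_26)
    if n == 0:
        return BinaryMask3D(np.zeros_like(vox, dtype=np.uint8), "spine", volume.spacing)
    nrow = vox.shape[1]
    keep = np.zeros(n + 1, dtype=bool)
    centroids = ndimage.center_of_mass(closed, labels, index=range(1, n + 1))
    for idx, (cz, crow, ccol) in enumerate(centroids, start=1):
        keep[idx] = crow > nrow / 2
    mask = keep[labels]
    return BinaryMask3D(mask.astype(np.uint8), "spine", volume.spacing)


def _spine_anterior_limit(spine: BinaryMask3D, nrow: int) -> float:
    if spine.is_empty():
        return nrow / 2
    return float(ndimage.center_of_mass(spine.voxels)[1])


def _find_seed(slice_hu: np.ndarray, cfg: ExpertConfig, anterior_limit: float,
               px_area_mm2: float) -> Optional[np.ndarray]:
    """Largest bright, round, anterior-of-spine component in the HU window."""
    lo, hi = cfg.lumen_window_hu
    nrow, ncol = slice_hu.shape
    in_window = (slice_hu >= lo) & (slice_hu <= hi)
    # restrict the search to the configured anterior band
    row_limit = anterior_limit * cfg.seed_search_fraction
    in_window[int(np.ceil(row_limit)):, :] = False
    if not in_window.any():
        return None
    labels = cc_label(in_window, connectivity=2)
    min_area_px = cfg.min_seed_area_mm2 / px_area_mm2
    candidates = []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        if rp.centroid[0] >= anterior_limit:
            continue
        if rp.eccentricity > cfg.max_seed_eccentricity:
            continue
        midline_dist = abs(rp.centroid[1] - ncol / 2)
        candidates.append((-rp.area, midline_dist, rp.label))
    if not candidates:
        return None
    candidates.sort()
    best = candidates[0][2]
    return labels == best


def _acwe_slice(slice_hu: np.ndarray, init: np.ndarray, cfg: ExpertConfig) -> np.ndarray:
    lo, hi = cfg.lumen_clip_hu
    img = np.clip(slice_hu, lo, hi).astype(np.float64)
    out = morphological_chan_vese(img, num_iter=cfg.acwe_iterations,
                                  init_level_set=init.astype(np.uint8),
                                  smoothing=cfg.acwe_smoothing)
    return out.astype(bool)


def _dice2d(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / s


def segment_lumen(volume: CTVolume, spine: BinaryMask3D, cfg: ExpertConfig,
                  seed_mask: Optional[np.ndarray] = None,
                  seed_slice: Optional[int] = None,
                  seed_source: str = "expert-window") -> LumenResult:
    """Seeded active-contour lumen segmentation with slice propagation.

    The default seed is found by the brightness-window rule on the
    mid-volume slice; callers (the hybrid workflow) may inject their own
    ``seed_mask``/``seed_slice``, recorded in ``seed_source``.
    """
    vox = volume.voxels.astype(np.float32)
    nz, nrow, ncol = vox.shape
    row_mm, col_mm, _ = volume.spacing
    empty = lambda: BinaryMask3D(np.zeros_like(vox, dtype=np.uint8), "lumen", volume.spacing)

    # suppress bright bone so the region-based contour cannot creep into it
    work = vox.copy()
    if not spine.is_empty():
        work[spine.voxels.astype(bool)] = 0.0

    anterior_limit = _spine_anterior_limit(spine, nrow)

    if seed_mask is None:
        seed_slice = nz // 2
        seed_mask = _find_seed(work[seed_slice], cfg, anterior_limit, row_mm * col_mm)
        if seed_mask is None:
            return LumenResult(empty(), "lumen-not-found", seed_source=None)
    else:
        if seed_slice is None:
            raise ValueError("seed_mask requires seed_slice")
        seed_mask = seed_mask.astype(bool)
        if not seed_mask.any():
            return LumenResult(empty(), "lumen-not-found", seed_source=seed_source)

    out = np.zeros_like(vox, dtype=bool)
    converged = _acwe_slice(work[seed_slice], seed_mask, cfg)
    if not converged.any():
        return LumenResult(empty(), "lumen-not-found", seed_source=seed_source)
    out[seed_slice] = converged

    for direction in (1, -1):
        prev = out[seed_slice]
        z = seed_slice + direction
        while 0 <= z < nz:
            cur = _acwe_slice(work[z], prev, cfg)
            if not cur.any() or _dice2d(cur, prev) < cfg.propagation_overlap_min:
                break
            out[z] = cur
            prev = cur
            z += direction

    return LumenResult(BinaryMask3D(out.astype(np.uint8), "lumen", volume.spacing),
                       "ok", seed_source=seed_source, seed_slice=seed_slice)


def segment_thrombus(volume: CTVolume, lumen: BinaryMask3D, cfg: ExpertConfig) -> BinaryMask3D:
    """Morphological snake for the thrombus, initialized from the lumen.

    Per slice containing lumen: the initial region is the lumen dilated by
    ``thrombus_dilation_mm``; the image is clipped to a soft-tissue window
    and the lumen interior is in-painted with the median HU of the dilation
    annulus (the snake should settle on the soft-tissue crescent boundary,
    not the strong lumen edge); the converged region minus the lumen is the
    thrombus. Raises on an empty lumen: the snake is undefined without its
    initialization.
    """
    if lumen.is_empty():
        raise ValueError("thrombus segmentation requires a non-empty lumen mask")
    if lumen.voxels.shape != volume.voxels.shape:
        raise ValueError("lumen mask grid does not match the volume")

    vox = volume.voxels.astype(np.float32)
    nrow, ncol = vox.shape[1:]
    row_mm, col_mm, _ = volume.spacing
    r_px = max(int(round(cfg.thrombus_dilation_mm / ((row_mm + col_mm) / 2))), 1)
    elem = disk_element(r_px)
    lo, hi = cfg.thrombus_window_hu
    margin = r_px + 4

    out = np.zeros_like(vox, dtype=bool)
    for z in range(vox.shape[0]):
        lum = lumen.voxels[z].astype(bool)
        if not lum.any():
            continue
        init = ndimage.binary_dilation(lum, structure=elem)
        # evolve on a local crop so distant structures (spine, body outline)
        # cannot skew the outside mean of the region energy
        rr, cc = np.nonzero(init)
        r0, r1 = max(rr.min() - margin, 0), min(rr.max() + margin + 1, nrow)
        c0, c1 = max(cc.min() - margin, 0), min(cc.max() + margin + 1, ncol)
        raw = vox[z, r0:r1, c0:c1]
        img = np.clip(raw, lo, hi).astype(np.float64)
        lum_c = lum[r0:r1, c0:c1]
        init_c = init[r0:r1, c0:c1]
        # bright structures (bone, contrast lumen) are not thrombus
        # candidates; flatten anything saturating the soft-tissue window to
        # the local background level so it cannot skew the region means
        bright = raw >= hi
        plain = ~init_c & ~bright
        bg_est = np.median(img[plain]) if plain.any() else lo
        img[bright] = bg_est
        # in-paint the lumen plus its partial-volume edge ring with the
        # annulus median: the snake should settle on the crescent's outer
        # soft-tissue boundary, not the strong lumen edge
        edge_px = max(int(round(cfg.thrombus_inpaint_margin_mm / ((row_mm + col_mm) / 2))), 0)
        core = ndimage.binary_dilation(lum_c, structure=disk_element(edge_px)) if edge_px else lum_c
        annulus = init_c & ~core
        # selection-free gate before the snake: thrombus must elevate the
        # mean of the whole annulus above the local background
        ann_clean = annulus & ~bright
        if ann_clean.any() and plain.any():
            if img[ann_clean].mean() - img[plain].mean() < cfg.thrombus_min_annulus_contrast_hu:
                continue
        if annulus.any():
            img[core] = np.median(img[annulus])
        if cfg.thrombus_crop_smoothing_mm > 0:
            img = ndimage.gaussian_filter(
                img, cfg.thrombus_crop_smoothing_mm / ((row_mm + col_mm) / 2))
        region = morphological_chan_vese(img, num_iter=cfg.thrombus_acwe_iterations,
                                         init_level_set=init_c.astype(np.uint8),
                                         smoothing=cfg.thrombus_acwe_smoothing)
        region = region.astype(bool)
        thrombus_c = region & ~lum_c & ~core
        # contrast gate: with no HU separation between the converged region
        # and the local background, there is no thrombus on this slice
        outside = ~region
        if thrombus_c.any() and outside.any():
            if abs(img[thrombus_c].mean() - img[outside].mean()) < cfg.thrombus_min_contrast_hu:
                thrombus_c[:] = False
        if thrombus_c.any():
            # the in-painted ring between lumen and detected crescent is
            # thrombus wherever the crescent touches it: geodesic fill
            ring = core & ~lum_c
            seed = ndimage.binary_dilation(thrombus_c) & ring
            thrombus_c |= ndimage.binary_propagation(seed, mask=ring)
        out[z, r0:r1, c0:c1] = thrombus_c

    return BinaryMask3D(out.astype(np.uint8), "thrombus", volume.spacing)


def segment_all(volume: CTVolume, cfg: ExpertConfig) -> dict:
    """Run the full expert pipeline; returns masks plus the lumen status."""
    pre = preprocess(volume, cfg)
    spine = segment_spine(pre, cfg)
    lumen_res = segment_lumen(pre, spine, cfg)
    if lumen_res.found and not lumen_res.mask.is_empty():
        thrombus = segment_thrombus(pre, lumen_res.mask, cfg)
    else:
        thrombus = BinaryMask3D(np.zeros_like(volume.voxels, dtype=np.uint8),
                                "thrombus", volume.spacing)
    return {"spine": spine, "lumen": lumen_res.mask, "thrombus": thrombus,
            "lumen_status": lumen_res.status, "lumen_seed_source": lumen_res.seed_source}
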
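"""Hybrid workflow: network localization + expert-system refinement.

The network supplies robust localization (per-slice probability maps,
thresholded at 0.5); the rule pipeline supplies precise boundaries:

* **lumen** — predicted spine pixels are erased (set to 0 HU) from the
  volume, then the expert active-contour lumen segmentation is re-run on
  the filtered images with the network's largest predicted lumen component
  replacing the brightness-window seed search;
* **thrombus** — the thrombus network's thresholded prediction is cleaned
  by removing every connected component that does not touch the lumen and
  smoothing each axial cross-section with a moment-matched ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from .expert_system import ExpertConfig, LumenResult, preprocess, segment_lumen
from .imaging_io import BinaryMask3D, CTVolume
from .unet import UNet, predict_volume, threshold


@dataclass
class HybridConfig:
    """Trained models plus the post-processing tunables."""

    spine_model: Optional[UNet] = None
    lumen_model: Optional[UNet] = None
    thrombus_model: Optional[UNet] = None
    threshold: float = 0.5
    component_connectivity: int = 26
    interpolation: bool = True
    # replace a cross-section by its fitted ellipse only when the fit is
    # faithful; guards genuinely non-elliptic sections
    ellipse_min_dice: float = 0.6
    # sections already this close to their fitted ellipse are left untouched
    # (smoothing has nothing to fix; keeps elliptic sections fixed points)
    ellipse_keep_dice: float = 0.98

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.component_connectivity not in (6, 18, 26):
            raise ValueError("component_connectivity must be 6, 18 or 26")


def _connectivity_structure(conn: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[conn])


def erase_spine(volume: CTVolume, spine_mask: BinaryMask3D) -> CTVolume:
    """Set the voxels under the spine mask to 0 HU, leaving all others as-is."""
    if spine_mask.voxels.shape != volume.voxels.shape:
        raise ValueError(
            f"grid mismatch: volume {volume.voxels.shape} vs mask {spine_mask.voxels.shape}")
    out = volume.voxels.copy()
    out[spine_mask.voxels.astype(bool)] = 0.0
    return CTVolume(out, volume.spacing)


def _largest_component_seed(mask3d: np.ndarray) -> Optional[tuple[int, np.ndarray]]:
    """Slice index and in-slice mask of the largest predicted 2D component."""
    best = None
    for z in range(mask3d.shape[0]):
        sl = mask3d[z]
        if not sl.any():
            continue
        labels = cc_label(sl, connectivity=2)
        for rp in regionprops(labels):
            if best is None or rp.area > best[0]:
                best = (rp.area, z, labels == rp.label)
    if best is None:
        return None
    return best[1], best[2]


def segment_lumen_hybrid(volume: CTVolume, cfg: HybridConfig,
                         expert_cfg: ExpertConfig) -> LumenResult:
    """Network-seeded, expert-refined lumen segmentation.

    Falls back to the expert brightness-window seed search when the network
    predicts no lumen anywhere; the seed provenance is recorded in the
    result (``seed_source``: ``"network"`` or ``"expert-window"``).
    """
    if cfg.spine_model is None or cfg.lumen_model is None:
        raise ValueError("segment_lumen_hybrid requires trained spine and lumen models")

    spine_prob = predict_volume(cfg.spine_model, volume.voxels)
    spine_net = BinaryMask3D(threshold(spine_prob, cfg.threshold), "spine", volume.spacing)
    lumen_net = threshold(predict_volume(cfg.lumen_model, volume.voxels), cfg.threshold)

    filtered = erase_spine(volume, spine_net)
    pre = preprocess(filtered, expert_cfg)

    seed = _largest_component_seed(lumen_net)
    if seed is not None:
        z, seed_mask = seed
        return segment_lumen(pre, spine_net, expert_cfg,
                             seed_mask=seed_mask, seed_slice=z, seed_source="network")
    # network found nothing: fall back to the expert seed search
    return segment_lumen(pre, spine_net, expert_cfg)


def _fit_ellipse_mask(region: np.ndarray) -> Optional[np.ndarray]:
    """Fill the ellipse matching the region's second-order central moments.

    Moments of the pixel-center cloud are corrected for the finite pixel
    extent (+1/12 per axis) so a rasterized ellipse maps back onto itself.
    """
    rr, cc = np.nonzero(region)
    n = rr.size
    if n < 8:
        return None
    cr, ccol = rr.mean(), cc.mean()
    dr, dc = rr - cr, cc - ccol
    cov = np.array([[np.mean(dr * dr) + 1.0 / 12.0, np.mean(dr * dc)],
                    [np.mean(dr * dc), np.mean(dc * dc) + 1.0 / 12.0]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        return None
    # uniform ellipse with semi-axes a,b has eigenvalues a^2/4, b^2/4
    semi = 2.0 * np.sqrt(evals)
    rows, cols = region.shape
    r_idx = np.arange(rows)[:, None] - cr
    c_idx = np.arange(cols)[None, :] - ccol
    u = r_idx * evecs[0, 0] + c_idx * evecs[1, 0]
    v = r_idx * evecs[0, 1] + c_idx * evecs[1, 1]
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def _dice2d(a: np.ndarray, b: np.ndarray) -> float:
    s = int(a.sum()) + int(b.sum())
    return 1.0 if s == 0 else 2.0 * int(np.count_nonzero(a & b)) / s


def postprocess_thrombus(raw: BinaryMask3D, lumen: BinaryMask3D,
                         cfg: HybridConfig) -> BinaryMask3D:
    """Connected-component filtering plus per-slice elliptic smoothing.

    A component of the raw prediction is kept iff its 1-voxel dilation
    intersects the lumen (a crescent touches but does not overlap it).
    When interpolation is on, each axial cross-section of (kept thrombus
    union lumen) is replaced by its moment-matched filled ellipse minus the
    lumen, provided the ellipse reproduces the unsmoothed section with Dice
    above ``ellipse_min_dice``. The output never intersects the lumen.
    """
    if raw.voxels.shape != lumen.voxels.shape:
        raise ValueError("grid mismatch between raw thrombus and lumen")
    raw_b = raw.voxels.astype(bool) & ~lumen.voxels.astype(bool)
    if not raw_b.any():
        return BinaryMask3D(np.zeros_like(raw.voxels), "thrombus", raw.spacing)

    structure = _connectivity_structure(cfg.component_connectivity)
    labels, n = ndimage.label(raw_b, structure=structure)
    lumen_dil = ndimage.binary_dilation(lumen.voxels.astype(bool),
                                        structure=_connectivity_structure(26))
    touching = np.unique(labels[lumen_dil & (labels > 0)])
    kept = np.isin(labels, touching[touching > 0])

    if not cfg.interpolation:
        return BinaryMask3D(kept.astype(np.uint8), "thrombus", raw.spacing)

    out = np.zeros_like(kept)
    lum_b = lumen.voxels.astype(bool)
    for z in range(kept.shape[0]):
        thr_sl = kept[z]
        if not thr_sl.any():
            continue
        region = thr_sl | lum_b[z]
        ellipse = _fit_ellipse_mask(region)
        fit_dice = _dice2d(ellipse, region) if ellipse is not None else 0.0
        if cfg.ellipse_min_dice < fit_dice < cfg.ellipse_keep_dice:
            out[z] = ellipse & ~lum_b[z]
        else:
            out[z] = thr_sl
    return BinaryMask3D(out.astype(np.uint8), "thrombus", raw.spacing)


def segment_thrombus_hybrid(volume: CTVolume, lumen: BinaryMask3D,
                            cfg: HybridConfig) -> BinaryMask3D:
    """Per-slice thrombus prediction, thresholded at 0.5, then post-processed."""
    if cfg.thrombus_model is None:
        raise ValueError("segment_thrombus_hybrid requires a trained thrombus model")
    prob = predict_volume(cfg.thrombus_model, volume.voxels)
    raw = BinaryMask3D(threshold(prob, cfg.threshold), "thrombus", volume.spacing)
    return postprocess_thrombus(raw, lumen, cfg)


def segment_all_hybrid(volume: CTVolume, cfg: HybridConfig,
                       expert_cfg: ExpertConfig) -> dict:
    """Full hybrid pipeline: spine (network), lumen (hybrid), thrombus (hybrid)."""
    spine_prob = predict_volume(cfg.spine_model, volume.voxels)
    spine = BinaryMask3D(threshold(spine_prob, cfg.threshold), "spine", volume.spacing)
    lumen_res = segment_lumen_hybrid(volume, cfg, expert_cfg)
    if not lumen_res.mask.is_empty():
        thrombus = segment_thrombus_hybrid(volume, lumen_res.mask, cfg)
    else:
        thrombus = BinaryMask3D(np.zeros_like(volume.voxels, dtype=np.uint8),
                                "thrombus", volume.spacing)
    return {"spine": spine, "lumen": lumen_res.mask, "thrombus": thrombus,
            "lumen_status": lumen_res.status, "lumen_seed_source": lumen_res.seed_source}
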
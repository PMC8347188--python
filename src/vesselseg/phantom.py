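"""Synthetic abdominal CTA phantoms with ground-truth masks.

A phantom emulates the structures the segmentation pipeline cares about in a
contrast-enhanced abdominal CT: a bright contrast-filled aortic lumen running
through the volume (optionally with an aneurysmal bulge), a hypodense
crescent of intraluminal thrombus wrapped around the bulged lumen, a
posterior bony spine column with periodic inter-vertebral gaps, soft-tissue
background, and additive Gaussian noise.

Two acquisition regimes are modelled:

* ``aaa`` — good arterial contrast (lumen ~300 HU), thin slices, moderate
  noise; and
* ``ami`` — a degraded regime with lower lumen/background contrast
  (``contrast_scale`` < 1 scales the lumen-minus-background mean), thicker
  slices and doubled noise.

The generator is fully deterministic under its seed and is the ground-truth
oracle for every downstream test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .imaging_io import HU_MAX, HU_MIN, BinaryMask3D, CTVolume, write_nifti


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic abdomen.

    Geometry parameters are physical (mm) where they describe tissue sizes,
    and fractions of the slice extent where they describe positions, so the
    same spec scales from the 128 x 128 test grid to full 512 x 512.
    """

    slice_shape: tuple[int, int] = (128, 128)
    n_slices: int = 32
    spacing: tuple[float, float, float] = (0.8, 0.8, 2.0)  # (row, col, slice) mm

    # lumen centerline: position as (row, col) fractions of the slice,
    # with a sinusoidal left-right sway along z of amplitude curvature_mm
    lumen_center_frac: tuple[float, float] = (0.42, 0.5)
    lumen_curvature_mm: float = 3.0
    lumen_radius_mm: float = 8.0
    # aneurysmal bulge: Gaussian radius increase along z
    bulge_amplitude_mm: float = 4.0
    bulge_center_frac: float = 0.5
    bulge_sigma_frac: float = 0.12

    # crescent thrombus: an outer disk whose centre is offset from the lumen
    # centre (eccentric lumen, the classic aneurysm cross-section) minus the
    # lumen; thickness tapers from its maximum on the offset side to zero at
    # the internal tangent point, so the cross-section is exactly an
    # ellipse-minus-lumen crescent
    thrombus: bool = True
    thrombus_max_thickness_mm: float = 6.0
    # optional angular clipping of the crescent (360 = full eccentric ring)
    thrombus_extent_deg: float = 360.0
    # direction of the thick side, in the (row, col) plane: 0 deg = +col,
    # 90 deg = +row (posterior), -90 deg = -row (anterior)
    thrombus_orientation_deg: float = -90.0

    # posterior spine column
    spine_center_frac: tuple[float, float] = (0.75, 0.5)
    spine_radius_mm: float = 12.0
    spine_gap_period: int = 10     # one inter-vertebral gap slice every k slices
    spine_gap_thickness: int = 1

    # HU statistics: class means (noise is a single additive Gaussian field)
    hu_background: float = 40.0
    hu_bone: float = 700.0
    hu_lumen: float = 300.0
    hu_thrombus: float = 50.0
    noise_sd: float = 15.0
    contrast_scale: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 8:
            raise ValueError("n_slices must be >= 8")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (0.0 < self.contrast_scale <= 1.0):
            raise ValueError("contrast_scale must be in (0, 1]")

    @property
    def lumen_mean_hu(self) -> float:
        """Effective lumen mean after contrast scaling."""
        return self.hu_background + self.contrast_scale * (self.hu_lumen - self.hu_background)


def aaa_spec(**overrides) -> PhantomSpec:
    """Default good-contrast (AAA-like) phantom spec."""
    return PhantomSpec(**overrides)


def ami_spec(**overrides) -> PhantomSpec:
    """Degraded (AMI-like) spec: lower contrast, thicker slices, doubled noise."""
    params = dict(
        contrast_scale=0.5,
        noise_sd=30.0,
        spacing=(0.8, 0.8, 3.0),
    )
    params.update(overrides)
    return PhantomSpec(**params)


# jitter ranges for generate_dataset, per regime
AAA_JITTER: dict[str, tuple[float, float]] = {
    "lumen_radius_mm": (7.0, 9.0),
    "bulge_amplitude_mm": (3.0, 5.0),
    "thrombus_max_thickness_mm": (4.5, 7.0),
    "lumen_curvature_mm": (1.0, 4.0),
}
AMI_JITTER: dict[str, tuple[float, float]] = {
    **AAA_JITTER,
    "contrast_scale": (0.4, 0.6),
    "slice_mm": (2.0, 3.0),
    "noise_sd": (25.0, 35.0),
}


def _disk(rows: np.ndarray, cols: np.ndarray, center_rc: tuple[float, float],
          radius_px_rc: tuple[float, float]) -> np.ndarray:
    dr = (rows - center_rc[0]) / radius_px_rc[0]
    dc = (cols - center_rc[1]) / radius_px_rc[1]
    return dr * dr + dc * dc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, dict[str, BinaryMask3D]]:
    """Rasterize *spec* into a CT volume and its spine/lumen/thrombus masks.

    The volume is the per-class mean rasterization plus one additive
    Gaussian HU noise field of SD ``spec.noise_sd``, clamped to the valid HU
    range; with ``noise_sd = 0`` every voxel equals its class mean exactly.
    """
    nrow, ncol = spec.slice_shape
    nz = spec.n_slices
    row_mm, col_mm, _ = spec.spacing

    rows = np.arange(nrow, dtype=np.float64)[:, None]
    cols = np.arange(ncol, dtype=np.float64)[None, :]

    lumen = np.zeros((nz, nrow, ncol), dtype=bool)
    thrombus = np.zeros_like(lumen)
    spine = np.zeros_like(lumen)

    spine_rc = (spec.spine_center_frac[0] * nrow, spec.spine_center_frac[1] * ncol)
    spine_r_px = (spec.spine_radius_mm / row_mm, spec.spine_radius_mm / col_mm)
    if spine_rc[0] - spine_r_px[0] < nrow / 2:
        raise ValueError("spine extends into the anterior half of the slice")

    z_frac = (np.arange(nz) + 0.5) / nz
    bulge = spec.bulge_amplitude_mm * np.exp(
        -0.5 * ((z_frac - spec.bulge_center_frac) / spec.bulge_sigma_frac) ** 2)
    radius_mm = spec.lumen_radius_mm + bulge
    if spec.thrombus:
        thickness_mm = spec.thrombus_max_thickness_mm * bulge / max(spec.bulge_amplitude_mm, 1e-9)
        thickness_mm[thickness_mm < 0.5] = 0.0  # thrombus only inside the bulge
    else:
        thickness_mm = np.zeros(nz)

    sway_px = spec.lumen_curvature_mm / col_mm
    theta0 = np.deg2rad(spec.thrombus_orientation_deg)
    half_extent = np.deg2rad(spec.thrombus_extent_deg) / 2.0

    for z in range(nz):
        lc_row = spec.lumen_center_frac[0] * nrow
        lc_col = spec.lumen_center_frac[1] * ncol + sway_px * np.sin(2 * np.pi * z_frac[z])
        r_rc = (radius_mm[z] / row_mm, radius_mm[z] / col_mm)
        outer_mm = radius_mm[z] + thickness_mm[z]
        outer_rc = (outer_mm / row_mm, outer_mm / col_mm)

        if (lc_row - outer_rc[0] < 0 or lc_row + outer_rc[0] >= nrow
                or lc_col - outer_rc[1] < 0 or lc_col + outer_rc[1] >= ncol):
            raise ValueError("lumen/thrombus geometry exceeds the slice bounds")
        if lc_row + outer_rc[0] >= spine_rc[0] - spine_r_px[0]:
            raise ValueError("lumen/thrombus geometry collides with the spine column")

        lum = _disk(rows, cols, (lc_row, lc_col), r_rc)
        lumen[z] = lum
        if thickness_mm[z] > 0:
            # outer disk of radius r + T/2, centre offset by T/2 toward the
            # thick side: internally tangent to the lumen on the far side
            off_mm = thickness_mm[z] / 2.0
            oc_row = lc_row + (off_mm / row_mm) * np.sin(theta0)
            oc_col = lc_col + (off_mm / col_mm) * np.cos(theta0)
            r_out = radius_mm[z] + off_mm
            outer = _disk(rows, cols, (oc_row, oc_col), (r_out / row_mm, r_out / col_mm))
            thr = outer & ~lum
            if spec.thrombus_extent_deg < 360.0:
                ang = np.arctan2(rows - lc_row, cols - lc_col) - theta0
                ang = (ang + np.pi) % (2 * np.pi) - np.pi
                thr &= np.abs(ang) <= half_extent
            thrombus[z] = thr

        if (z % spec.spine_gap_period) >= spec.spine_gap_period - spec.spine_gap_thickness:
            continue  # inter-vertebral gap slice: no bone
        spine[z] = _disk(rows, cols, spine_rc, spine_r_px)

    hu = np.full((nz, nrow, ncol), spec.hu_background, dtype=np.float64)
    hu[thrombus] = spec.hu_thrombus
    hu[lumen] = spec.lumen_mean_hu
    hu[spine] = spec.hu_bone
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
    hu = np.clip(hu, HU_MIN, HU_MAX).astype(np.float32)

    volume = CTVolume(hu, spec.spacing)
    masks = {
        "spine": BinaryMask3D(spine.astype(np.uint8), "spine", spec.spacing),
        "lumen": BinaryMask3D(lumen.astype(np.uint8), "lumen", spec.spacing),
        "thrombus": BinaryMask3D(thrombus.astype(np.uint8), "thrombus", spec.spacing),
    }
    return volume, masks


def _apply_jitter(base: PhantomSpec, params: Mapping[str, float], seed: int) -> PhantomSpec:
    updates: dict = {"seed": seed}
    spacing = list(base.spacing)
    for key, value in params.items():
        if key == "slice_mm":
            spacing[2] = float(value)
        elif key == "row_mm":
            spacing[0] = float(value)
        elif key == "col_mm":
            spacing[1] = float(value)
        else:
            if not hasattr(base, key):
                raise KeyError(f"unknown PhantomSpec jitter parameter {key!r}")
            updates[key] = float(value)
    updates["spacing"] = tuple(spacing)
    return dataclasses.replace(base, **updates)


def generate_dataset(
    n_volumes: int,
    base_spec: PhantomSpec | None = None,
    jitter: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[tuple[PhantomSpec, CTVolume, dict[str, BinaryMask3D]]]:
    """Generate *n_volumes* phantoms with parameters jittered around *base_spec*.

    Each volume's spec is sampled uniformly from the ``jitter`` ranges (keyed
    by PhantomSpec field name, plus ``slice_mm``/``row_mm``/``col_mm`` for
    individual spacing components) using a master RNG seeded with *seed*;
    per-volume noise seeds are derived from the same master RNG, so the whole
    dataset is reproducible. With no jitter, every volume uses the base
    parameters exactly (noise seeds still differ per volume).
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    base_spec = base_spec or PhantomSpec()
    jitter = dict(jitter or {})
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_volumes):
        params = {k: rng.uniform(lo, hi) for k, (lo, hi) in jitter.items()}
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = _apply_jitter(base_spec, params, child_seed)
        vol, masks = generate_phantom(spec)
        out.append((spec, vol, masks))
    return out


def write_dataset(dataset, out_dir) -> Path:
    """Write a generated dataset as NIfTI files plus a TSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (spec, vol, masks) in enumerate(dataset):
        vol_path = out_dir / f"phantom_{i:03d}.nii.gz"
        write_nifti(vol, vol_path)
        mask_paths = {}
        for label, mask in masks.items():
            mp = out_dir / f"phantom_{i:03d}_{label}.nii.gz"
            write_nifti(mask, mp)
            mask_paths[label] = mp.name
        rows.append({
            "volume": vol_path.name,
            **{f"mask_{k}": v for k, v in mask_paths.items()},
            "seed": spec.seed,
            "contrast_scale": spec.contrast_scale,
            "noise_sd": spec.noise_sd,
            "slice_mm": spec.spacing[2],
            "lumen_radius_mm": spec.lumen_radius_mm,
        })
    manifest = out_dir / "manifest.tsv"
    cols = list(rows[0].keys())
    with open(manifest, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    return manifest
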
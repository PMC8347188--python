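"""Segmentation evaluation metrics and paired method comparison.

Implements the standard overlap metrics (Dice, Jaccard, sensitivity,
specificity), volume similarity, and the Hausdorff distance between mask
boundaries, plus a paired two-tailed Student's t-test harness for comparing
two segmentation methods slice by slice.

Degenerate denominators are never silently dropped: each metric carries an
``undefined`` flag, with two documented conventions — Dice of two empty
masks is 1 (perfect agreement on absence), and Dice of an empty prediction
against a non-empty truth is 0, so failed slices are scored, not excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imaging_io import BinaryMask3D

METRIC_NAMES = ("dice", "jaccard", "sensitivity", "specificity",
                "volume_similarity", "hausdorff")


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask3D):
        return mask.voxels.astype(bool)
    return np.asarray(mask).astype(bool)


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Exact voxel-wise (TP, FP, FN, TN) between two binary fields."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return tp, fp, fn, tn


def overlap_metrics(counts: tuple[int, int, int, int]) -> tuple[dict, set]:
    """Dice, Jaccard, sensitivity, specificity from confusion counts.

    Returns the metric dict and a set of metric names whose denominator was
    degenerate. Conventions: both masks empty -> dice = jaccard = 1;
    empty prediction vs non-empty truth -> dice = jaccard = 0.
    """
    tp, fp, fn, tn = counts
    out: dict[str, float] = {}
    undefined: set[str] = set()

    if tp + fp + fn == 0:
        out["dice"] = 1.0
        out["jaccard"] = 1.0
        undefined |= {"dice", "jaccard"}  # flagged: by-convention values
    else:
        out["dice"] = 2 * tp / (2 * tp + fp + fn)
        out["jaccard"] = tp / (tp + fp + fn)

    if tp + fn == 0:
        out["sensitivity"] = math.nan
        undefined.add("sensitivity")
    else:
        out["sensitivity"] = tp / (tp + fn)

    if tn + fp == 0:
        out["specificity"] = math.nan
        undefined.add("specificity")
    else:
        out["specificity"] = tn / (tn + fp)
    return out, undefined


def volume_similarity(counts: tuple[int, int, int, int]) -> tuple[float, bool]:
    """VS = 1 - |FN - FP| / (2TP + FP + FN).

    Equals ``1 - |V_pred - V_truth| / (V_pred + V_truth)``: it compares
    segment volumes only and is 1 whenever the volumes agree, regardless of
    overlap. Returns (value, undefined_flag); both masks empty is undefined.
    """
    tp, fp, fn, _ = counts
    denom = 2 * tp + fp + fn
    if denom == 0:
        return math.nan, True
    return 1.0 - abs(fn - fp) / denom, False


def _boundary(mask: np.ndarray) -> np.ndarray:
    # voxels of the set not fully surrounded by the set (array edge counts
    # as background, so edge-touching foreground is boundary)
    return mask & ~ndimage.binary_erosion(mask, border_value=0)


def hausdorff(pred, truth, spacing=None, units: str = "voxel") -> tuple[float, bool]:
    """Symmetric Hausdorff distance between the boundaries of two masks.

    ``max(sup_a inf_b d(a, b), sup_b inf_a d(a, b))`` over boundary voxels,
    Euclidean *d*. In ``voxel`` units index deltas count as 1 per axis; in
    ``mm`` units deltas are scaled by the grid spacing (requires *spacing*
    as ``(row_mm, col_mm, slice_mm)`` or BinaryMask3D inputs).

    Returns (value, undefined_flag); undefined when either mask is empty.
    """
    if units not in ("voxel", "mm"):
        raise ValueError(f"units must be 'voxel' or 'mm', got {units!r}")
    if spacing is None and isinstance(pred, BinaryMask3D):
        spacing = pred.spacing
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        return math.nan, True
    if units == "mm":
        if spacing is None:
            raise ValueError("mm units require spacing")
        row_mm, col_mm, slice_mm = spacing
        sampling = (slice_mm, row_mm, col_mm) if p.ndim == 3 else (row_mm, col_mm)
    else:
        sampling = (1.0,) * p.ndim

    bp, bt = _boundary(p), _boundary(t)
    d_to_t = ndimage.distance_transform_edt(~bt, sampling=sampling)
    d_to_p = ndimage.distance_transform_edt(~bp, sampling=sampling)
    return float(max(d_to_t[bp].max(), d_to_p[bt].max())), False


@dataclass
class MetricsReport:
    """All metrics for one (prediction, truth) pair."""

    tp: int
    fp: int
    fn: int
    tn: int
    dice: float
    jaccard: float
    sensitivity: float
    specificity: float
    volume_similarity: float
    hausdorff: float
    undefined: set = field(default_factory=set)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def evaluate(pred, truth, spacing=None, hausdorff_units: str = "voxel") -> MetricsReport:
    """Compute the full MetricsReport for one (prediction, truth) pair."""
    counts = confusion_counts(pred, truth)
    overlap, undef = overlap_metrics(counts)
    vs, vs_undef = volume_similarity(counts)
    if vs_undef:
        undef.add("volume_similarity")
    hd, hd_undef = hausdorff(pred, truth, spacing=spacing, units=hausdorff_units)
    if hd_undef:
        undef.add("hausdorff")
    return MetricsReport(*counts, dice=overlap["dice"], jaccard=overlap["jaccard"],
                         sensitivity=overlap["sensitivity"],
                         specificity=overlap["specificity"],
                         volume_similarity=vs, hausdorff=hd, undefined=undef)


@dataclass
class ComparisonResult:
    """Paired comparison of two methods over matched slices/volumes."""

    per_metric: dict
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        """One row per metric: mean +/- SD and min-max per method, plus p."""
        rows = []
        for name, st in self.per_metric.items():
            rows.append({
                "metric": name,
                "mean_a": st["mean_a"], "sd_a": st["sd_a"],
                "min_a": st["min_a"], "max_a": st["max_a"],
                "mean_b": st["mean_b"], "sd_b": st["sd_b"],
                "min_b": st["min_b"], "max_b": st["max_b"],
                "t": st["t"], "p": st["p"], "n": st["n"],
                "degenerate": st["degenerate"],
            })
        return pd.DataFrame(rows).set_index("metric")


def compare_methods(reports_a: Sequence[MetricsReport],
                    reports_b: Sequence[MetricsReport]) -> ComparisonResult:
    """Paired two-tailed Student's t-test per metric between two methods.

    ``t = mean(d) / (sd(d) / sqrt(n))`` on the paired differences with
    ``n - 1`` degrees of freedom. Pairs where either report flags the metric
    undefined are excluded for that metric (count kept in the result). A
    zero-variance difference vector is flagged degenerate: p = 1 when all
    differences are zero (identical methods), NaN otherwise.
    """
    if len(reports_a) != len(reports_b):
        raise ValueError("paired reports must have equal length")
    if len(reports_a) < 2:
        raise ValueError("need at least 2 paired reports")

    per_metric = {}
    for name in METRIC_NAMES:
        pairs = [(getattr(ra, name), getattr(rb, name))
                 for ra, rb in zip(reports_a, reports_b)
                 if name not in ra.undefined and name not in rb.undefined]
        st: dict = {"n": len(pairs), "degenerate": False}
        if len(pairs) < 2:
            st.update(dict.fromkeys(
                ["mean_a", "sd_a", "min_a", "max_a",
                 "mean_b", "sd_b", "min_b", "max_b", "t", "p"], math.nan))
            st["degenerate"] = True
            per_metric[name] = st
            continue
        a = np.array([p[0] for p in pairs], dtype=float)
        b = np.array([p[1] for p in pairs], dtype=float)
        d = a - b
        st.update(mean_a=a.mean(), sd_a=a.std(ddof=1), min_a=a.min(), max_a=a.max(),
                  mean_b=b.mean(), sd_b=b.std(ddof=1), min_b=b.min(), max_b=b.max())
        if np.allclose(d.std(ddof=1), 0.0):
            st["degenerate"] = True
            if np.allclose(d, 0.0):
                st["t"], st["p"] = 0.0, 1.0
            else:
                st["t"], st["p"] = math.inf if d.mean() > 0 else -math.inf, math.nan
        else:
            t_stat, p_val = stats.ttest_rel(a, b)
            st["t"], st["p"] = float(t_stat), float(p_val)
        per_metric[name] = st
    return ComparisonResult(per_metric=per_metric, n=len(reports_a))
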
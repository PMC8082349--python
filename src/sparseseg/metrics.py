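"""Segmentation evaluation: Dice, sensitivity, undirected 95th-percentile
Hausdorff distance.

Conventions (each carried through batch reports as flags, never dropped
silently):

- ``dice(m, a) = 2 TP / (2 TP + FP + FN)``; both masks empty -> 1.0, flagged.
- ``sensitivity(m, a) = TP / (TP + FN)``; empty manual mask -> NaN sentinel.
- ``hd95``: boundary voxels are extracted with 6-connectivity (a mask voxel
  is boundary iff any face neighbor is background or volume edge); distances
  between boundary voxel centers are measured in mm with anisotropic
  spacing; the *undirected* value is the maximum of the two directed 95th
  percentiles, each computed with linear interpolation between order
  statistics.  (A pooled-percentile variant is available via
  ``method="pooled"``.)  Either mask empty -> NaN sentinel.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import SegmentationMask

HD95_UNDEFINED = float("nan")


@dataclasses.dataclass
class MetricTriple:
    dice: float
    sensitivity: float
    hd95: float
    tp: int
    fp: int
    fn: int
    flags: tuple[str, ...] = ()


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.voxels.astype(bool)
    return np.asarray(mask).astype(bool)


def _check_grids(manual, automatic):
    m, a = _as_bool(manual), _as_bool(automatic)
    if m.shape != a.shape:
        raise ValueError(f"grid mismatch: {m.shape} vs {a.shape}")
    if isinstance(manual, SegmentationMask) and isinstance(automatic, SegmentationMask):
        if not np.allclose(manual.spacing, automatic.spacing, rtol=1e-4):
            raise ValueError(f"spacing mismatch: {manual.spacing} vs {automatic.spacing}")
    return m, a


def _counts(m: np.ndarray, a: np.ndarray):
    tp = int(np.count_nonzero(m & a))
    fp = int(np.count_nonzero(~m & a))
    fn = int(np.count_nonzero(m & ~a))
    return tp, fp, fn


def dice(manual, automatic) -> float:
    """Dice overlap 2·TP/(2·TP+FP+FN); two empty masks score 1.0."""
    m, a = _check_grids(manual, automatic)
    tp, fp, fn = _counts(m, a)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def sensitivity(manual, automatic) -> float:
    """Recall TP/(TP+FN); NaN when the manual mask is empty."""
    m, a = _check_grids(manual, automatic)
    tp, fp, fn = _counts(m, a)
    return HD95_UNDEFINED if tp + fn == 0 else tp / (tp + fn)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of mask voxels with a 6-neighbor outside the mask (or edge)."""
    m = np.asarray(mask).astype(bool)
    interior = np.ones_like(m)
    for ax in range(3):
        lo = np.roll(m, 1, axis=ax)
        hi = np.roll(m, -1, axis=ax)
        # voxels on the volume edge have an out-of-volume neighbor
        idx_lo = [slice(None)] * 3
        idx_lo[ax] = 0
        idx_hi = [slice(None)] * 3
        idx_hi[ax] = -1
        lo[tuple(idx_lo)] = False
        hi[tuple(idx_hi)] = False
        interior &= lo & hi
    return np.argwhere(m & ~interior)


def _directed_p95(src_pts: np.ndarray, dst_tree: cKDTree) -> float:
    d, _ = dst_tree.query(src_pts, k=1)
    return float(np.percentile(d, 95.0))


def hd95_undirected(manual, automatic, spacing=None, method: str = "max") -> float:
    """Undirected 95th-percentile Hausdorff distance in mm.

    ``method="max"`` (default) takes the maximum of the two directed 95th
    percentiles; ``method="pooled"`` takes the 95th percentile of the pooled
    directed distance set.  NaN if either mask is empty.
    """
    m, a = _check_grids(manual, automatic)
    if spacing is None:
        spacing = manual.spacing if isinstance(manual, SegmentationMask) else (1.0,) * 3
    if not m.any() or not a.any():
        return HD95_UNDEFINED
    sp = np.asarray(spacing, dtype=float)
    pm = boundary_voxels(m) * sp
    pa = boundary_voxels(a) * sp
    tree_m, tree_a = cKDTree(pm), cKDTree(pa)
    if method == "max":
        return max(_directed_p95(pa, tree_m), _directed_p95(pm, tree_a))
    if method == "pooled":
        d_am, _ = tree_m.query(pa, k=1)
        d_ma, _ = tree_a.query(pm, k=1)
        return float(np.percentile(np.concatenate([d_am, d_ma]), 95.0))
    raise ValueError(f"unknown method {method!r}")


def evaluate_pair(manual, automatic, spacing=None) -> MetricTriple:
    """All three measures from one pass of voxel counts."""
    m, a = _check_grids(manual, automatic)
    if spacing is None:
        spacing = manual.spacing if isinstance(manual, SegmentationMask) else (1.0,) * 3
    tp, fp, fn = _counts(m, a)
    flags = []
    denom = 2 * tp + fp + fn
    if denom == 0:
        d = 1.0
        flags.append("both_empty")
    else:
        d = 2.0 * tp / denom
    if tp + fn == 0:
        sens = HD95_UNDEFINED
        if denom != 0:
            flags.append("manual_empty")
    else:
        sens = tp / (tp + fn)
    if m.any() and a.any():
        h = hd95_undirected(m, a, spacing=spacing)
    else:
        h = HD95_UNDEFINED
        flags.append("hd95_undefined")
    return MetricTriple(dice=d, sensitivity=sens, hd95=h, tp=tp, fp=fp, fn=fn,
                        flags=tuple(flags))


def evaluate_batch(pairs: Sequence[tuple], spacing=None,
                   subject_ids: Optional[Sequence[str]] = None,
                   model_id: str = "", missing_pattern: str = "") -> pd.DataFrame:
    """Tidy per-pair metric table for a batch of (manual, automatic) masks."""
    rows = []
    for i, (m, a) in enumerate(pairs):
        t = evaluate_pair(m, a, spacing=spacing)
        rows.append({
            "subject_id": subject_ids[i] if subject_ids else str(i),
            "model_id": model_id,
            "missing_pattern": missing_pattern,
            "dice": t.dice, "sensitivity": t.sensitivity, "hd95": t.hd95,
            "tp": t.tp, "fp": t.fp, "fn": t.fn,
            "flags": "|".join(t.flags),
        })
    return pd.DataFrame(rows)
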
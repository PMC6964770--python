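"""Segmentation evaluation: Dice, sensitivity, specificity, Hausdorff, ASSD.

Distance metrics operate on the full foreground voxel sets (every labeled
voxel, not only the surface), in voxel units by default; pass a spacing
to measure in mm, or ``surface=True`` for the boundary-voxel convention.

Conventions for degenerate inputs are explicit because phantoms with zero
tumors occur: Dice of two empty sets is 1.0; other zero-denominator
ratios return NaN (flagged via log); distance metrics on an empty set
raise :class:`EmptySetError`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import LabelVolume, check_aligned

log = logging.getLogger(__name__)


class EmptySetError(ValueError):
    """Distance between voxel sets is undefined when a set is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, LabelVolume) else np.asarray(x)


def confusion(pred, truth, positive_class: int) -> ConfusionCounts:
    """Exact voxel counts treating one class as positive."""
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pp = p == positive_class
    tt = t == positive_class
    return ConfusionCounts(
        tp=int(np.count_nonzero(pp & tt)),
        tn=int(np.count_nonzero(~pp & ~tt)),
        fp=int(np.count_nonzero(pp & ~tt)),
        fn=int(np.count_nonzero(~pp & tt)),
    )


def dice(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); 1.0 when both sets are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN if no actual positives."""
    if c.tp + c.fn == 0:
        log.warning("sensitivity undefined: no positive voxels in truth")
        return math.nan
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN if no actual negatives."""
    if c.tn + c.fp == 0:
        log.warning("specificity undefined: no negative voxels in truth")
        return math.nan
    return c.tn / (c.tn + c.fp)


def _voxel_coords(mask: np.ndarray, spacing=None) -> np.ndarray:
    pts = np.argwhere(mask).astype(np.float64)
    if spacing is not None:
        pts *= np.asarray(spacing, dtype=np.float64)[None, :]
    return pts


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded


def _point_sets(sg, sp, spacing, surface):
    a = np.asarray(sg, dtype=bool)
    b = np.asarray(sp, dtype=bool)
    if surface:
        a, b = _surface(a), _surface(b)
    pa, pb = _voxel_coords(a, spacing), _voxel_coords(b, spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise EmptySetError("distance metrics need two non-empty voxel sets")
    return pa, pb


def _directed_min_dists(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """For each point of pa, the Euclidean distance to its nearest point of pb."""
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return d


def hausdorff(sg, sp, spacing=None, surface: bool = False) -> float:
    """Symmetric Hausdorff distance max(h(sg,sp), h(sp,sg)) over voxel sets."""
    pa, pb = _point_sets(sg, sp, spacing, surface)
    return float(max(_directed_min_dists(pa, pb).max(),
                     _directed_min_dists(pb, pa).max()))


def assd(sg, sp, spacing=None, surface: bool = False, literal: bool = False) -> float:
    """Average symmetric distance between two voxel sets.

    Default (standard ASSD): the mean of all nearest-neighbour distances
    pooled from both directions,
    (sum_a min_b ||a-b|| + sum_b min_a ||b-a||) / (N1 + N2).
    ``literal=True`` instead divides the two per-set *averaged* distances
    by (N1 + N2), a double-normalized variant kept for comparison.
    """
    pa, pb = _point_sets(sg, sp, spacing, surface)
    d_ab = _directed_min_dists(pa, pb)
    d_ba = _directed_min_dists(pb, pa)
    n1, n2 = len(pa), len(pb)
    if literal:
        return float((d_ab.mean() + d_ba.mean()) / (n1 + n2))
    return float((d_ab.sum() + d_ba.sum()) / (n1 + n2))


@dataclass
class MetricsReport:
    """Per-class evaluation of a predicted segmentation against truth."""

    classes: dict[str, dict[str, float]]
    units: str = "voxels"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def evaluate(pred: LabelVolume, truth: LabelVolume,
             class_labels: dict[str, int] | None = None,
             spacing=None, surface: bool = False) -> MetricsReport:
    """Full metric suite for each requested class.

    Distance metrics are skipped (NaN) for classes empty in either volume.
    """
    check_aligned(pred, truth)
    if class_labels is None:
        class_labels = {"liver": 1, "tumor": 2}
    out: dict[str, dict[str, float]] = {}
    for name, lab in class_labels.items():
        c = confusion(pred, truth, lab)
        row = {
            "dice": dice(c),
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
        }
        try:
            row["hausdorff"] = hausdorff(truth.data == lab, pred.data == lab,
                                         spacing=spacing, surface=surface)
            row["assd"] = assd(truth.data == lab, pred.data == lab,
                               spacing=spacing, surface=surface)
        except EmptySetError:
            log.warning("class %s empty in prediction or truth; distances undefined", name)
            row["hausdorff"] = math.nan
            row["assd"] = math.nan
        out[name] = row
    return MetricsReport(classes=out, units="mm" if spacing is not None else "voxels")
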
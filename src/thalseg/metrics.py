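"""Evaluation metrics and nucleus-to-group label unification.

Ground-truth labels are sparse (only high-confidence voxels annotated), so
overlap metrics that penalize predictions at unlabeled voxels would be
misleading; the primary accuracy metric is therefore the per-class true
positive rate (TPR) over labeled ground-truth voxels, summarized per subject
as a volume-weighted average (VWA). Test–retest agreement uses the Dice
coefficient between repeated-scan segmentations, and longitudinal volume
stability uses the coefficient of variation (CV) of structure volumes across
repeated scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .types import DomainError, SENTINEL, UsageError, check_hard_labels, check_sparse_labels

__all__ = [
    "tpr",
    "per_class_tpr",
    "volume_weighted_average",
    "vwa_tpr",
    "dice",
    "volume_cv",
    "GroupingScheme",
    "apply_grouping",
    "default_grouping",
]


def tpr(pred: np.ndarray, gt: np.ndarray, cls: int) -> float:
    """True positive rate for one class over labeled ground-truth voxels.

    ``|{gt == cls and pred == cls}| / |{gt == cls}|``; sentinel and
    other-class ground-truth voxels never enter the denominator. Raises if
    the class is absent from the ground truth (the rate is undefined, not 0).
    """
    pred = check_hard_labels(pred)
    gt = check_sparse_labels(gt)
    if pred.shape != gt.shape:
        raise UsageError("grids are misaligned")
    gt_mask = gt == cls
    n = int(gt_mask.sum())
    if n == 0:
        raise DomainError(f"class {cls} absent from ground truth: TPR undefined")
    return float((pred[gt_mask] == cls).sum() / n)


def per_class_tpr(pred: np.ndarray, gt: np.ndarray, classes=None):
    """TPR and ground-truth voxel count per present class.

    Returns ``{cls: (tpr, n_gt_voxels)}`` over the requested classes
    (default: all non-background, non-sentinel classes present in ``gt``);
    absent classes are omitted ("missing"), not reported as 0.
    """
    gt = check_sparse_labels(gt)
    if classes is None:
        classes = [c for c in np.unique(gt) if c not in (0, SENTINEL)]
    out = {}
    for cls in classes:
        n = int((gt == cls).sum())
        if n == 0:
            continue
        out[int(cls)] = (tpr(pred, gt, int(cls)), n)
    return out


def volume_weighted_average(values, weights) -> float:
    """Weighted mean ``sum(w_i v_i) / sum(w_i)`` with nonnegative weights."""
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if values.shape != weights.shape:
        raise UsageError("values and weights must match")
    if np.any(weights < 0):
        raise UsageError("weights must be nonnegative")
    total = weights.sum()
    if total == 0:
        raise UsageError("weights must not all be zero")
    return float((values * weights).sum() / total)


def vwa_tpr(pred: np.ndarray, gt: np.ndarray) -> float:
    """Volume-weighted-average TPR, weighted by ground-truth voxel counts."""
    scores = per_class_tpr(pred, gt)
    if not scores:
        raise DomainError("no foreground classes present in ground truth")
    vals = [v for v, _ in scores.values()]
    wts = [n for _, n in scores.values()]
    return volume_weighted_average(vals, wts)


def dice(seg_a: np.ndarray, seg_b: np.ndarray, cls: int) -> float | None:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` for one class; None if both empty."""
    seg_a = check_hard_labels(seg_a)
    seg_b = check_hard_labels(seg_b)
    if seg_a.shape != seg_b.shape:
        raise UsageError("grids are misaligned")
    a = seg_a == cls
    b = seg_b == cls
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def volume_cv(series) -> float:
    """Coefficient of variation (%) of a volume series across repeated scans.

    ``100 * sample_std / mean`` with the n−1 denominator; needs >= 2
    measurements and a positive mean.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise UsageError("need a 1D series of length >= 2")
    if np.any(series < 0):
        raise UsageError("volumes must be nonnegative")
    mean = series.mean()
    if mean <= 0:
        raise DomainError("zero mean volume: CV undefined")
    return float(100.0 * series.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Label-scheme unification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupingScheme:
    """Mapping from nucleus label to group id, with group names.

    ``mapping`` maps source labels (1–13) to group ids; labels without an
    entry pass through unchanged. Background 0 and the sentinel are never
    remapped.
    """

    mapping: dict[int, int]
    group_names: dict[int, str]

    def __post_init__(self) -> None:
        if 0 in self.mapping or SENTINEL in self.mapping:
            raise UsageError("background and sentinel cannot be remapped")

    @classmethod
    def from_yaml(cls, path) -> "GroupingScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        names = {int(k): str(v) for k, v in raw["groups"].items()}
        mapping = {int(k): int(v) for k, v in raw["mapping"].items()}
        return cls(mapping=mapping, group_names=names)


def default_grouping() -> GroupingScheme:
    """The shipped 13-nuclei → 7-group scheme (editable configuration).

    The nucleus-to-group assignment is protocol configuration, not code; the
    default file is a best-effort anatomical assignment that users should
    edit to match their own protocol.
    """
    ref = resources.files("thalseg").joinpath("data/grouping7.yaml")
    with resources.as_file(ref) as path:
        return GroupingScheme.from_yaml(path)


def apply_grouping(seg: np.ndarray, scheme: GroupingScheme) -> np.ndarray:
    """Voxelwise relabeling; background and sentinel pass through unchanged."""
    seg = check_sparse_labels(seg)
    lut = np.arange(SENTINEL + 1, dtype=np.int16)
    for src, dst in scheme.mapping.items():
        lut[src] = dst
    return lut[seg]
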
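"""Two sequential anatomical-plausibility refinements of hard segmentations.

Step 1 (thalamus-level filtering) binarizes nuclei-vs-background and erases
any 6-connected foreground component smaller than 200 voxels — spurious
predictions far from the thalamus. Step 2 (nucleus-level refinement) removes,
per class, 6-connected components smaller than 10 voxels and reassigns each
such island as a whole to the candidate class — among the labels of its
6-connected neighbor voxels — with the highest mean predicted probability
over the island. Both size predicates are strict ("smaller than"), so
components of exactly the threshold size are retained.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import N_CLASSES, UsageError, check_hard_labels

__all__ = ["thalamus_filter", "nucleus_refine", "postprocess", "CONNECTIVITY_6"]

#: 6-connectivity structuring element (face neighbors only).
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


def thalamus_filter(seg: np.ndarray, min_size: int = 200) -> np.ndarray:
    """Erase small isolated foreground components of the binarized segmentation.

    Any 6-connected component of the nuclei mask (labels 1–13 vs background)
    with fewer than ``min_size`` voxels is set to background; larger
    components are untouched.
    """
    seg = check_hard_labels(seg)
    fg = seg > 0
    comp, n = ndimage.label(fg, structure=CONNECTIVITY_6)
    if n == 0:
        return seg.copy()
    sizes = np.bincount(comp.reshape(-1))
    small = sizes < min_size
    small[0] = False
    out = seg.copy()
    out[small[comp]] = 0
    return out


def nucleus_refine(
    seg: np.ndarray, probs: np.ndarray, min_size: int = 10, per_voxel: bool = False
) -> np.ndarray:
    """Reassign small per-class islands to their most probable neighbor class.

    For each class c in 1–13 (processed in ascending order against the
    original segmentation, edits applied to a copy): each 6-connected
    component of ``{seg == c}`` smaller than ``min_size`` voxels is
    reassigned to the candidate class with the highest mean predicted
    probability over the component's voxels, where candidates are the labels
    of voxels 6-adjacent to (and outside) the component. Ties break toward
    the lower class index. With ``per_voxel=True`` each island voxel is
    instead reassigned individually to its own most probable candidate.
    """
    seg = check_hard_labels(seg)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 4 or probs.shape[0] != N_CLASSES:
        raise UsageError(f"expected ({N_CLASSES}, D, H, W) probabilities")
    if probs.shape[1:] != seg.shape:
        raise UsageError("segmentation and probabilities are misaligned")
    out = seg.copy()
    for cls in range(1, N_CLASSES):
        mask = seg == cls
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=CONNECTIVITY_6)
        sizes = np.bincount(comp.reshape(-1))
        for ci in range(1, n + 1):
            if sizes[ci] >= min_size:
                continue
            island = comp == ci
            ring = ndimage.binary_dilation(island, structure=CONNECTIVITY_6) & ~island
            candidates = np.unique(seg[ring])
            if candidates.size == 0:
                continue
            if per_voxel:
                sub = probs[np.ix_(candidates, *[np.arange(s) for s in seg.shape])]
                choice = candidates[np.argmax(sub, axis=0)[island]]
                out[island] = choice
            else:
                mean_p = [probs[c][island].mean() for c in candidates]
                out[island] = candidates[int(np.argmax(mean_p))]
    return out


def postprocess(
    seg: np.ndarray,
    probs: np.ndarray,
    min_thalamus: int = 200,
    min_nucleus: int = 10,
    per_voxel: bool = False,
) -> np.ndarray:
    """Thalamus-level filtering followed by nucleus-level refinement."""
    return nucleus_refine(
        thalamus_filter(seg, min_thalamus), probs, min_nucleus, per_voxel
    )
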
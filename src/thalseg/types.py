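"""Core domain types shared across the pipeline.

Volumes are plain 3D :class:`numpy.ndarray` grids wrapped in light dataclasses
that carry the metadata the physics cares about: voxel spacing, whether signal
polarity has been restored, and per-voxel validity of fitted parameter maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Number of segmentation classes: background (0) plus 13 thalamic nuclei.
N_CLASSES = 14

#: Label value marking unlabeled-within-thalamus voxels, excluded from supervision.
SENTINEL = 100

#: Labels a dense (hard) segmentation may contain.
VALID_HARD_LABELS = frozenset(range(N_CLASSES))

#: Labels a sparse annotation volume may contain.
VALID_SPARSE_LABELS = frozenset(range(N_CLASSES)) | {SENTINEL}


class DomainError(ValueError):
    """A physically or mathematically invalid input (e.g. non-positive T1)."""


class UsageError(ValueError):
    """An API misuse (shape mismatch, wrong flag state, bad configuration)."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Inversion-recovery acquisition timing.

    Parameters
    ----------
    tr : float
        Repetition time in milliseconds. Must be positive.
    ti : float
        Inversion time in milliseconds. Must satisfy ``0 < ti < tr``.
    """

    tr: float
    ti: float

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise DomainError(f"tr must be positive, got {self.tr}")
        if not 0 < self.ti < self.tr:
            raise DomainError(f"ti must lie in (0, tr)={(0, self.tr)}, got {self.ti}")


@dataclass
class ScalarVolume:
    """A 3D intensity grid with voxel spacing and a polarity flag.

    ``signed=False`` means the values are magnitudes (as stored by the
    scanner); ``signed=True`` means polarity has been restored so values may
    be negative.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    signed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise UsageError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise UsageError(f"grid dimensions must be >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class QMaps:
    """Voxelwise quantitative maps: T1 (ms), proton density (a.u.), validity.

    ``valid`` is False where the fit failed (degenerate signal, no root,
    parameter pinned at a bound); T1/PD values there are unspecified and
    downstream synthesis emits zeros.
    """

    t1: np.ndarray
    pd: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=np.float64)
        self.pd = np.asarray(self.pd, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t1.shape == self.pd.shape == self.valid.shape):
            raise UsageError("t1, pd and valid must share one grid shape")
        if np.any(self.t1[self.valid] <= 0):
            raise DomainError("valid voxels must have t1 > 0")
        if np.any(self.pd[self.valid] < 0):
            raise DomainError("valid voxels must have pd >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape  # type: ignore[return-value]


@dataclass
class BiasField:
    """Multiplicative gain field; strictly positive, smooth by construction."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise UsageError("bias field must be a 3D grid")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise DomainError("bias field must be strictly positive and finite")


@dataclass
class WmStats:
    """White-matter mask and its mean intensity on the reference image."""

    mask: np.ndarray
    mean_intensity: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DomainError("white-matter mask is empty")
        if not self.mean_intensity > 0:
            raise DomainError("mean WM intensity must be positive")


def check_sparse_labels(labels: np.ndarray) -> np.ndarray:
    """Validate a sparse label grid ({0..13} ∪ {100}) and return it as int16."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise UsageError("label grid must be 3D")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise UsageError("label grid contains non-integral values")
    labels = labels.astype(np.int16)
    present = set(np.unique(labels).tolist())
    bad = present - VALID_SPARSE_LABELS
    if bad:
        raise UsageError(f"invalid label values present: {sorted(bad)}")
    return labels


def check_hard_labels(seg: np.ndarray) -> np.ndarray:
    """Validate a hard segmentation grid ({0..13}) and return it as int16."""
    seg = check_sparse_labels(seg)
    if (seg == SENTINEL).any():
        raise UsageError("hard segmentation must not contain the sentinel value 100")
    return seg
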
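"""Harmonized dual-modality bias correction, WM normalization, and cropping.

The two acquisitions differ only in inversion time, so their quantitative
relationship must survive preprocessing. Bias fields are estimated per
modality, combined into a single harmonized field as their voxelwise
geometric mean ``B_harm = sqrt(B_M * B_F)``, and the SAME field divides both
images. Intensities are then put on a common scale by dividing both images
by the mean white-matter intensity of the bias-corrected MPRAGE, with the WM
mask obtained by fuzzy C-means clustering.
"""

from __future__ import annotations

import numpy as np

from .types import BiasField, DomainError, ScalarVolume, UsageError, WmStats

__all__ = [
    "estimate_bias",
    "harmonize_bias",
    "fuzzy_c_means",
    "wm_mask_fcm",
    "wm_normalize",
    "center_crop",
    "pad_back",
    "crop_slices",
]


# ---------------------------------------------------------------------------
# Bias field estimation (pluggable contract)
# ---------------------------------------------------------------------------

def _foreground_mask(values: np.ndarray, frac: float = 0.01) -> np.ndarray:
    """Voxels above ``frac`` of the robust (99.9th percentile) maximum."""
    robust_max = np.percentile(values, 99.9)
    if robust_max <= 0:
        raise UsageError("image has no positive foreground")
    return values > frac * robust_max


def _poly_design(shape: tuple[int, ...], order: int = 2) -> np.ndarray:
    """Low-order 3D polynomial design matrix on normalized [-1, 1] coords."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((zz**i) * (yy**j) * (xx**k))
    return np.stack([c.reshape(-1) for c in cols], axis=1)


def estimate_bias_poly(image: ScalarVolume, order: int = 2) -> BiasField:
    """Polynomial log-domain bias estimator (self-contained, no externals).

    Fits a low-order 3D polynomial to the log-intensity of foreground voxels
    and exponentiates it, normalized to unit geometric mean over the
    foreground. Smooth by construction; suitable for synthetic data and
    testing. Real scans are better served by the N4 estimator.
    """
    vals = image.values
    if np.any(vals < 0):
        raise UsageError("bias estimation expects a non-negative image")
    if not np.any(vals > 0):
        raise UsageError("cannot estimate bias on an all-zero image")
    fg = _foreground_mask(vals)
    design = _poly_design(vals.shape, order)
    logv = np.log(vals.reshape(-1)[fg.reshape(-1)])
    coef, *_ = np.linalg.lstsq(design[fg.reshape(-1)], logv, rcond=None)
    logb = design @ coef
    logb -= logb[fg.reshape(-1)].mean()  # unit geometric mean on foreground
    return BiasField(values=np.exp(logb).reshape(vals.shape))


def estimate_bias_n4(image: ScalarVolume, shrink: int = 2) -> BiasField:
    """N4 bias estimator via SimpleITK (production path for real scans)."""
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise UsageError("the 'n4' bias method requires SimpleITK") from exc
    vals = image.values
    if not np.any(vals > 0):
        raise UsageError("cannot estimate bias on an all-zero image")
    img = sitk.GetImageFromArray(vals.astype(np.float32))
    mask = sitk.GetImageFromArray(_foreground_mask(vals).astype(np.uint8))
    small = sitk.Shrink(img, [shrink] * 3)
    small_mask = sitk.Shrink(mask, [shrink] * 3)
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.Execute(small, small_mask)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(log_field)).astype(np.float64)
    return BiasField(values=field)


_BIAS_ESTIMATORS = {"poly": estimate_bias_poly, "n4": estimate_bias_n4}


def estimate_bias(image: ScalarVolume, method: str = "poly", **kwargs) -> BiasField:
    """Estimate a multiplicative bias field with the named estimator.

    ``method='poly'`` (default) is the built-in polynomial log-domain
    estimator; ``method='n4'`` calls N4 through SimpleITK.
    """
    try:
        fn = _BIAS_ESTIMATORS[method]
    except KeyError:
        raise UsageError(
            f"unknown bias method {method!r}; available: {sorted(_BIAS_ESTIMATORS)}"
        ) from None
    return fn(image, **kwargs)


def harmonize_bias(
    img_m: ScalarVolume,
    img_f: ScalarVolume,
    bias_m: BiasField,
    bias_f: BiasField,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Correct both modalities with the geometric mean of their bias fields.

    ``B_harm = sqrt(B_M * B_F)`` voxelwise; both images are divided by the
    same harmonized field, so their voxelwise ratio is preserved exactly.
    """
    shapes = {img_m.shape, img_f.shape, bias_m.values.shape, bias_f.values.shape}
    if len(shapes) != 1:
        raise UsageError("images and bias fields must share one grid shape")
    if np.any(bias_m.values <= 0) or np.any(bias_f.values <= 0):
        raise DomainError("bias fields must be strictly positive")
    b_harm = np.sqrt(bias_m.values * bias_f.values)
    out_m = ScalarVolume(img_m.values / b_harm, img_m.spacing, img_m.signed)
    out_f = ScalarVolume(img_f.values / b_harm, img_f.spacing, img_f.signed)
    return out_m, out_f


# ---------------------------------------------------------------------------
# Fuzzy C-means white-matter masking and normalization
# ---------------------------------------------------------------------------

def fuzzy_c_means(
    x: np.ndarray,
    n_classes: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """1D fuzzy C-means on a sample vector.

    Returns ``(centroids, memberships)`` with centroids sorted ascending and
    memberships of shape ``(n_classes, len(x))``. Centroids are initialised
    at the 0.25/0.5/0.75 intensity quantiles (evenly spaced quantiles for
    other class counts), making the procedure deterministic.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    if x.size < n_classes:
        raise UsageError("fewer samples than classes")
    if np.ptp(x) == 0:
        raise DomainError("intensity distribution too degenerate to cluster")
    qs = np.linspace(0, 1, n_classes + 2)[1:-1]
    centroids = np.quantile(x, qs)
    if np.unique(centroids).size < n_classes:
        # heavily skewed histogram: fall back to evenly spaced centroids
        centroids = np.linspace(x.min(), x.max(), n_classes + 2)[1:-1]
    expo = 2.0 / (m - 1.0)
    u = None
    for _ in range(max_iter):
        d = np.abs(x[None, :] - centroids[:, None])
        d = np.maximum(d, 1e-12)
        inv = d ** (-expo)
        u_new = inv / inv.sum(axis=0, keepdims=True)
        um = u_new**m
        centroids_new = (um @ x) / um.sum(axis=1)
        shift = np.max(np.abs(centroids_new - centroids))
        centroids = centroids_new
        if u is not None and shift < tol:
            u = u_new
            break
        u = u_new
    order = np.argsort(centroids)
    return centroids[order], u[order]


def wm_mask_fcm(img_m: ScalarVolume, n_classes: int = 3) -> WmStats:
    """White-matter mask from the MPRAGE by fuzzy C-means on foreground voxels.

    WM is the hard assignment to the class with the highest centroid (WM is
    the brightest tissue on MPRAGE); the returned statistics carry the mean
    image intensity over that mask.
    """
    vals = img_m.values
    fg = _foreground_mask(vals)
    samples = vals[fg]
    if np.ptp(samples) == 0:
        raise DomainError("constant foreground: clustering cannot separate tissues")
    _, u = fuzzy_c_means(samples, n_classes=n_classes)
    hard = np.argmax(u, axis=0)
    wm_flat = hard == n_classes - 1  # highest centroid after ascending sort
    mask = np.zeros(vals.shape, dtype=bool)
    mask[fg] = wm_flat
    if not mask.any():
        raise DomainError("fuzzy C-means produced an empty white-matter class")
    return WmStats(mask=mask, mean_intensity=float(vals[mask].mean()))


def wm_normalize(
    img_m: ScalarVolume, img_f: ScalarVolume, stats: WmStats
) -> tuple[ScalarVolume, ScalarVolume]:
    """Divide both images by the MPRAGE mean white-matter intensity."""
    if not stats.mean_intensity > 0:
        raise DomainError("mean WM intensity must be positive")
    mu = stats.mean_intensity
    return (
        ScalarVolume(img_m.values / mu, img_m.spacing, img_m.signed),
        ScalarVolume(img_f.values / mu, img_f.spacing, img_f.signed),
    )


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop_slices(
    shape: tuple[int, ...], size: tuple[int, ...]
) -> tuple[slice, ...]:
    """Centered crop window; an odd surplus drops the extra voxel high-side.

    For input extent N and crop extent n the low-side offset is
    ``(N - n) // 2``, so e.g. 97 → 96 keeps indices 0..95.
    """
    if len(shape) != len(size):
        raise UsageError("shape and size must have equal rank")
    slices = []
    for n_in, n_out in zip(shape, size):
        if n_out > n_in:
            raise UsageError(f"crop size {n_out} exceeds input extent {n_in}")
        lo = (n_in - n_out) // 2
        slices.append(slice(lo, lo + n_out))
    return tuple(slices)


def center_crop(vol, size):
    """Center-crop a 3D array or :class:`ScalarVolume` to ``size`` per axis."""
    size = tuple(int(s) for s in np.broadcast_to(size, (3,)))
    if isinstance(vol, ScalarVolume):
        sl = crop_slices(vol.shape, size)
        return ScalarVolume(vol.values[sl].copy(), vol.spacing, vol.signed)
    arr = np.asarray(vol)
    sl = crop_slices(arr.shape, size)
    return arr[sl].copy()


def pad_back(cropped, original_shape, fill=0):
    """Inverse of :func:`center_crop`: re-embed into the original extent.

    Voxels outside the crop window take ``fill`` (0 for both images and
    labels by default).
    """
    original_shape = tuple(int(s) for s in original_shape)
    if isinstance(cropped, ScalarVolume):
        inner = pad_back(cropped.values, original_shape, fill)
        return ScalarVolume(inner, cropped.spacing, cropped.signed)
    arr = np.asarray(cropped)
    sl = crop_slices(original_shape, arr.shape)
    out = np.full(original_shape, fill, dtype=arr.dtype)
    out[sl] = arr
    return out
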
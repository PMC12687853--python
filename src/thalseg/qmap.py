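"""Inversion-recovery signal model, T1/PD estimation and multi-TI synthesis.

The signal of a T1-weighted inversion-recovery acquisition at a voxel with
proton density ``PD`` and longitudinal relaxation time ``T1`` is modeled as

    I = PD * (1 - 2*exp(-TI/T1) + exp(-TR/T1))

Two acquisitions sharing TR but with different TI (an MPRAGE at long TI and a
white-matter-nulled FGATIR at short TI) give two measurements per voxel, from
which (PD, T1) are recovered by nonlinear least squares. Because scanners
store magnitudes, the FGATIR volume — whose tissues sit at negative
longitudinal magnetization at short TI — must have its polarity restored
(negated) before fitting. From the fitted maps, synthetic magnitude images at
arbitrary inversion times ("multi-TI" images) are computed with the same
model; sweeping TI nulls different tissues and enhances intra-thalamic
contrast.
"""

from __future__ import annotations

import numpy as np

from .types import AcquisitionParams, DomainError, QMaps, ScalarVolume, UsageError

__all__ = [
    "ir_signal",
    "null_ti",
    "restore_polarity",
    "fit_qmaps",
    "synthesize_multi_ti",
    "default_ti_grid",
]

#: Default T1 fit bounds in milliseconds.
T1_BOUNDS = (200.0, 5000.0)


def _bracket(t1, ti, tr):
    """The TI/TR-dependent factor 1 - 2 exp(-TI/T1) + exp(-TR/T1)."""
    t1 = np.asarray(t1, dtype=np.float64)
    return 1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)


def _bracket_dt1(t1, ti, tr):
    """d/dT1 of :func:`_bracket` (analytic, used by the Gauss-Newton fit)."""
    t1 = np.asarray(t1, dtype=np.float64)
    return (-2.0 * ti * np.exp(-ti / t1) + tr * np.exp(-tr / t1)) / t1**2


def ir_signal(pd, t1, acq: AcquisitionParams):
    """Signed inversion-recovery signal ``PD * (1 - 2 e^{-TI/T1} + e^{-TR/T1})``.

    Parameters are broadcast; ``t1`` must be positive everywhere. The result
    may be negative for short TI (tissue still inverted at readout).
    """
    t1 = np.asarray(t1, dtype=np.float64)
    if np.any(t1 <= 0):
        raise DomainError("t1 must be positive")
    out = np.asarray(pd, dtype=np.float64) * _bracket(t1, acq.ti, acq.tr)
    return out if out.ndim else float(out)


def null_ti(t1: float, tr: float) -> float:
    """Inversion time that nulls tissue with relaxation time ``t1`` at ``tr``.

    Solves ``1 - 2 exp(-TI/T1) + exp(-TR/T1) = 0`` for TI, which has the
    closed form ``TI* = T1 * ln(2 / (1 + exp(-TR/T1)))``. As TR → ∞ this
    tends to the classic null point ``T1 ln 2``.
    """
    if t1 <= 0:
        raise DomainError("t1 must be positive")
    if tr <= 0:
        raise DomainError("tr must be positive")
    ti = t1 * np.log(2.0 / (1.0 + np.exp(-tr / t1)))
    if not 0.0 < ti < tr:
        raise DomainError(
            f"no null inversion time in (0, tr) for t1={t1}, tr={tr}"
        )
    return float(ti)


def restore_polarity(fgatir_magnitude: ScalarVolume) -> ScalarVolume:
    """Negate an FGATIR magnitude volume, restoring the signed signal.

    At the short FGATIR inversion time most brain tissue has negative
    longitudinal magnetization, so the signed signal is the negated magnitude.
    The assumption holds for tissues with long T1 (thalamus, cortex) and not
    for very short-T1 tissue such as fat; the whole volume is negated.
    """
    if fgatir_magnitude.signed:
        raise UsageError("volume polarity already restored")
    return ScalarVolume(
        values=-np.abs(fgatir_magnitude.values),
        spacing=fgatir_magnitude.spacing,
        signed=True,
    )


def _t1_grid_scan(im, if_, acq_m, acq_f, bounds, n_nodes=96):
    """Vectorized bracketing + bisection for the PD-cancelling ratio equation.

    PD cancels in the ratio of the two measurements, leaving the scalar
    equation ``g(T1) = IM * f_F(T1) - IF * f_M(T1) = 0`` per voxel (written
    multiplicatively to avoid dividing by a nulled signal). A log-spaced scan
    locates a sign change, refined by bisection. Voxels without a sign change
    are flagged invalid.
    """
    lo, hi = bounds
    nodes = np.geomspace(lo, hi, n_nodes)

    def g(t1):
        return im * _bracket(t1, acq_f.ti, acq_f.tr) - if_ * _bracket(
            t1, acq_m.ti, acq_m.tr
        )

    gv = np.stack([g(t) for t in nodes], axis=0)  # (n_nodes, n_vox)
    sign_change = np.signbit(gv[:-1]) != np.signbit(gv[1:])
    has_root = sign_change.any(axis=0)
    first = np.argmax(sign_change, axis=0)
    a = nodes[first]
    b = nodes[first + 1]
    ga = np.take_along_axis(gv, first[None], axis=0)[0]
    for _ in range(52):
        mid = 0.5 * (a + b)
        gm = g(mid)
        left = np.signbit(ga) != np.signbit(gm)
        b = np.where(left, mid, b)
        a = np.where(left, a, mid)
        ga = np.where(left, ga, gm)
    t1 = 0.5 * (a + b)
    return t1, has_root


def fit_qmaps(
    mprage: ScalarVolume,
    fgatir_signed: ScalarVolume,
    acq_m: AcquisitionParams,
    acq_f: AcquisitionParams,
    t1_bounds: tuple[float, float] = T1_BOUNDS,
    n_gn_iter: int = 8,
) -> QMaps:
    """Per-voxel nonlinear least-squares estimation of (PD, T1).

    Two instances of the inversion-recovery signal equation (one per
    acquisition) are fitted jointly at every voxel. The solver is a
    vectorized Gauss-Newton iteration on the 2-parameter problem with an
    analytic Jacobian, initialised from the PD-cancelling ratio equation
    (bracketing scan + bisection in T1, then the closed-form least-squares PD
    given T1). Voxels where no ratio root exists in the T1 bounds, where both
    measurements vanish, or where the solution pins at a bound are flagged
    ``valid=False``.
    """
    if mprage.shape != fgatir_signed.shape:
        raise UsageError("mprage and fgatir volumes must share a shape")
    if acq_m.tr != acq_f.tr:
        raise UsageError("the two acquisitions must share TR")
    if acq_m.ti == acq_f.ti:
        raise UsageError("the two acquisitions must differ in TI")
    if not fgatir_signed.signed:
        raise UsageError("fgatir polarity must be restored before fitting")

    shape = mprage.shape
    im = mprage.values.reshape(-1)
    iff = fgatir_signed.values.reshape(-1)

    degenerate = (im == 0) & (iff == 0)
    t1, has_root = _t1_grid_scan(im, iff, acq_m, acq_f, t1_bounds)
    t1 = np.clip(t1, *t1_bounds)

    fm = _bracket(t1, acq_m.ti, acq_m.tr)
    ff = _bracket(t1, acq_f.ti, acq_f.tr)
    denom = fm**2 + ff**2
    with np.errstate(invalid="ignore", divide="ignore"):
        pd = np.where(denom > 0, (im * fm + iff * ff) / np.maximum(denom, 1e-300), 0.0)

    # Gauss-Newton refinement of (pd, t1); residuals r = pd*f(t1; acq) - I.
    for _ in range(n_gn_iter):
        fm = _bracket(t1, acq_m.ti, acq_m.tr)
        ff = _bracket(t1, acq_f.ti, acq_f.tr)
        dm = _bracket_dt1(t1, acq_m.ti, acq_m.tr)
        df = _bracket_dt1(t1, acq_f.ti, acq_f.tr)
        r1 = pd * fm - im
        r2 = pd * ff - iff
        # Normal equations for J^T J delta = -J^T r with J rows (f, pd*f').
        a11 = fm**2 + ff**2
        a12 = pd * (fm * dm + ff * df)
        a22 = pd**2 * (dm**2 + df**2)
        b1 = -(r1 * fm + r2 * ff)
        b2 = -(r1 * pd * dm + r2 * pd * df)
        det = a11 * a22 - a12**2
        ok = det > 1e-300
        with np.errstate(invalid="ignore", divide="ignore"):
            d_pd = np.where(ok, (b1 * a22 - b2 * a12) / np.where(ok, det, 1.0), 0.0)
            d_t1 = np.where(ok, (b2 * a11 - b1 * a12) / np.where(ok, det, 1.0), 0.0)
        pd = pd + d_pd
        t1 = np.clip(t1 + d_t1, *t1_bounds)

    eps_bound = 1e-9
    at_bound = (t1 <= t1_bounds[0] * (1 + eps_bound)) | (
        t1 >= t1_bounds[1] * (1 - eps_bound)
    )
    valid = has_root & ~degenerate & ~at_bound & (pd > 0) & np.isfinite(pd)
    t1 = np.where(valid, t1, np.nan)
    pd = np.where(valid, pd, np.nan)
    # NaNs at invalid voxels are replaced by neutral placeholders.
    t1 = np.where(valid, t1, 1000.0)
    pd = np.where(valid, pd, 0.0)

    return QMaps(
        t1=t1.reshape(shape),
        pd=pd.reshape(shape),
        valid=valid.reshape(shape),
        spacing=mprage.spacing,
    )


def default_ti_grid(start: float = 400.0, stop: float = 1400.0, step: float = 20.0):
    """Inclusive TI grid; the default sweeps 400–1400 ms in 20 ms steps (51 images)."""
    n = int(round((stop - start) / step)) + 1
    return [start + i * step for i in range(n)]


def synthesize_multi_ti(
    maps: QMaps, acq_tr: float, ti_grid: list[float] | None = None
) -> list[ScalarVolume]:
    """Synthesize magnitude images at each TI from fitted (PD, T1) maps.

    For each grid TI the signed signal is evaluated with TR fixed and the
    absolute value taken (clinical scanners store magnitudes). Invalid voxels
    are emitted as 0.
    """
    if ti_grid is None:
        ti_grid = default_ti_grid()
    if len(ti_grid) == 0:
        raise UsageError("TI grid must be non-empty")
    for ti in ti_grid:
        if not 0 < ti < acq_tr:
            raise UsageError(f"grid TI {ti} outside (0, tr={acq_tr})")
    t1 = np.where(maps.valid, maps.t1, 1000.0)
    pd = np.where(maps.valid, maps.pd, 0.0)
    out = []
    for ti in ti_grid:
        sig = np.abs(ir_signal(pd, t1, AcquisitionParams(tr=acq_tr, ti=ti)))
        sig[~maps.valid] = 0.0
        out.append(ScalarVolume(values=sig, spacing=maps.spacing, signed=False))
    return out
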
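"""Inversion-recovery signal model, null points, polarity, and the T1/PD fit."""

import numpy as np
import pytest
from scipy.optimize import brentq

import thalseg as ts
from thalseg.qmap import _bracket

MPRAGE = ts.AcquisitionParams(tr=4000.0, ti=1400.0)
FGATIR = ts.AcquisitionParams(tr=4000.0, ti=400.0)


class TestIrSignal:
    @pytest.mark.parametrize(
        "pd, t1, acq, expected",
        [
            (0.0, 1000.0, MPRAGE, 0.0),
            (1.0, 1000.0, MPRAGE, 0.5251217110),
            (1.0, 1000.0, FGATIR, -0.3223244532),
        ],
    )
    def test_closed_form_values(self, pd, t1, acq, expected):
        assert ts.ir_signal(pd, t1, acq) == pytest.approx(expected, abs=1e-9)

    def test_linear_in_pd(self):
        base = ts.ir_signal(1.0, 1200.0, MPRAGE)
        for k in (0.5, 2.0, 7.3):
            assert ts.ir_signal(k, 1200.0, MPRAGE) == pytest.approx(k * base)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ts.DomainError):
            ts.ir_signal(1.0, 0.0, MPRAGE)
        with pytest.raises(ts.DomainError):
            ts.ir_signal(1.0, -100.0, MPRAGE)

    def test_monotone_in_t1_within_one_signed_regime(self):
        # With TI=1400/TR=4000 the bracket stays positive for T1 < ~2000 ms
        # and the signal decreases monotonically with T1 there.
        t1 = np.linspace(300, 1900, 200)
        sig = ts.ir_signal(1.0, t1, MPRAGE)
        assert np.all(sig > 0)
        assert np.all(np.diff(sig) < 0)


class TestNullTi:
    def test_against_bisection_oracle(self):
        # independent oracle: bisection on the signal bracket
        for t1, tr in [(1000.0, 4000.0), (700.0, 3000.0), (1500.0, 6000.0)]:
            oracle = brentq(
                lambda ti: _bracket(t1, ti, tr), 1e-6, tr - 1e-6, xtol=1e-12
            )
            assert ts.null_ti(t1, tr) == pytest.approx(oracle, abs=1e-9)

    def test_known_value(self):
        assert ts.null_ti(1000.0, 4000.0) == pytest.approx(675.0, abs=0.05)

    def test_long_tr_limit_is_t1_ln2(self):
        assert ts.null_ti(1000.0, 1e9) == pytest.approx(1000.0 * np.log(2), rel=1e-9)

    def test_returned_ti_nulls_the_signal(self):
        ti = ts.null_ti(1234.0, 4000.0)
        sig = ts.ir_signal(1.0, 1234.0, ts.AcquisitionParams(tr=4000.0, ti=ti))
        assert abs(sig) < 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ts.DomainError):
            ts.null_ti(-5.0, 4000.0)
        with pytest.raises(ts.DomainError):
            ts.null_ti(1000.0, 0.0)


class TestRestorePolarity:
    def test_constant_volume_negated(self):
        vol = ts.ScalarVolume(np.full((3, 3, 3), 5.0))
        out = ts.restore_polarity(vol)
        assert out.signed
        assert np.all(out.values == -5.0)

    def test_zero_volume_stays_zero(self):
        out = ts.restore_polarity(ts.ScalarVolume(np.zeros((2, 2, 2))))
        assert np.all(out.values == 0.0)

    def test_round_trip_with_signal_model(self):
        # |signal| at short TI, re-negated, equals the signed model value
        signed = ts.ir_signal(1.0, 1000.0, FGATIR)
        assert signed < 0
        mag = ts.ScalarVolume(np.full((2, 2, 2), abs(signed)))
        out = ts.restore_polarity(mag)
        assert np.allclose(out.values, signed)

    def test_double_restore_rejected(self):
        out = ts.restore_polarity(ts.ScalarVolume(np.ones((2, 2, 2))))
        with pytest.raises(ts.UsageError):
            ts.restore_polarity(out)


def _signed_pair(t1, pd):
    im = ts.ir_signal(pd, t1, MPRAGE)
    iff = ts.ir_signal(pd, t1, FGATIR)
    return (
        ts.ScalarVolume(im, signed=True),
        ts.ScalarVolume(iff, signed=True),
    )


class TestFitQmaps:
    def test_noiseless_single_value_roundtrip(self):
        m, f = _signed_pair(np.full((2, 2, 2), 1000.0), np.ones((2, 2, 2)))
        maps = ts.fit_qmaps(m, f, MPRAGE, FGATIR)
        assert maps.valid.all()
        assert np.allclose(maps.t1, 1000.0, rtol=1e-6)
        assert np.allclose(maps.pd, 1.0, rtol=1e-6)

    def test_ratio_rootfind_oracle_equivalence(self):
        # independent oracle: PD cancels in the measurement ratio, leaving a
        # 1-D root problem in T1 solved here by brentq
        t1_true = np.array([420.0, 900.0, 1600.0, 2800.0])
        pd_true = np.array([0.6, 1.0, 1.3, 0.9])
        im = ts.ir_signal(pd_true, t1_true, MPRAGE)
        iff = ts.ir_signal(pd_true, t1_true, FGATIR)
        maps = ts.fit_qmaps(
            ts.ScalarVolume(im.reshape(1, 2, 2), signed=True),
            ts.ScalarVolume(iff.reshape(1, 2, 2), signed=True),
            MPRAGE,
            FGATIR,
        )
        for k in range(4):
            oracle_t1 = brentq(
                lambda t: im[k] * _bracket(t, FGATIR.ti, FGATIR.tr)
                - iff[k] * _bracket(t, MPRAGE.ti, MPRAGE.tr),
                200.0,
                5000.0,
                xtol=1e-10,
            )
            assert maps.t1.reshape(-1)[k] == pytest.approx(oracle_t1, rel=1e-6)

    def test_zero_signal_voxel_invalid(self):
        t1 = np.full((2, 2, 2), 1000.0)
        pd = np.ones((2, 2, 2))
        pd[0, 0, 0] = 0.0
        m, f = _signed_pair(t1, pd)
        maps = ts.fit_qmaps(m, f, MPRAGE, FGATIR)
        assert not maps.valid[0, 0, 0]
        assert maps.valid.reshape(-1)[1:].all()

    def test_scaling_inputs_scales_pd_only(self):
        t1 = np.linspace(500, 2000, 8).reshape(2, 2, 2)
        pd = np.full((2, 2, 2), 0.8)
        m, f = _signed_pair(t1, pd)
        maps1 = ts.fit_qmaps(m, f, MPRAGE, FGATIR)
        k = 3.7
        m2 = ts.ScalarVolume(k * m.values, signed=True)
        f2 = ts.ScalarVolume(k * f.values, signed=True)
        maps2 = ts.fit_qmaps(m2, f2, MPRAGE, FGATIR)
        assert np.allclose(maps2.t1, maps1.t1, rtol=1e-9)
        assert np.allclose(maps2.pd, k * maps1.pd, rtol=1e-9)

    def test_usage_errors(self):
        m, f = _signed_pair(np.full((2, 2, 2), 1000.0), np.ones((2, 2, 2)))
        with pytest.raises(ts.UsageError):
            ts.fit_qmaps(m, ts.ScalarVolume(np.ones((3, 3, 3)), signed=True), MPRAGE, FGATIR)
        with pytest.raises(ts.UsageError):
            ts.fit_qmaps(m, f, MPRAGE, MPRAGE)
        with pytest.raises(ts.UsageError):
            ts.fit_qmaps(m, ts.ScalarVolume(np.abs(f.values)), MPRAGE, FGATIR)
        with pytest.raises(ts.UsageError):
            ts.fit_qmaps(
                m, f, ts.AcquisitionParams(tr=5000, ti=1400), FGATIR
            )


class TestSynthesizeMultiTi:
    def _maps(self):
        t1 = np.linspace(800, 1500, 27).reshape(3, 3, 3)
        pd = np.full((3, 3, 3), 0.9)
        return ts.QMaps(t1=t1, pd=pd, valid=np.ones((3, 3, 3), bool)), t1, pd

    def test_consistency_with_signal_model_at_mprage_ti(self):
        maps, t1, pd = self._maps()
        (img,) = ts.synthesize_multi_ti(maps, 4000.0, [1400.0])
        expected = np.abs(ts.ir_signal(pd, t1, MPRAGE))
        assert np.allclose(img.values, expected)

    def test_outputs_nonnegative_and_invalid_voxels_zero(self):
        maps, _, _ = self._maps()
        maps.valid[1, 1, 1] = False
        stack = ts.synthesize_multi_ti(maps, 4000.0, [500.0, 900.0])
        for img in stack:
            assert np.all(img.values >= 0)
            assert img.values[1, 1, 1] == 0.0

    def test_nulling_at_null_ti(self):
        maps, t1, _ = self._maps()
        ti_star = ts.null_ti(float(t1[0, 0, 0]), 4000.0)
        (img,) = ts.synthesize_multi_ti(maps, 4000.0, [ti_star])
        assert img.values[0, 0, 0] < 1e-9
        assert img.values[2, 2, 2] > 1e-3

    def test_default_grid_has_51_images(self):
        grid = ts.default_ti_grid()
        assert len(grid) == 51
        assert grid[0] == 400.0 and grid[-1] == 1400.0 and grid[1] - grid[0] == 20.0

    def test_empty_grid_rejected(self):
        maps, _, _ = self._maps()
        with pytest.raises(ts.UsageError):
            ts.synthesize_multi_ti(maps, 4000.0, [])


def test_roundtrip_grid_signed_inputs():
    """Noiseless simulation over a (pd, t1) grid refits to < 1e-6 relative."""
    t1 = np.linspace(300, 3000, 100).reshape(4, 5, 5)
    pd = np.linspace(0.5, 1.5, 100).reshape(4, 5, 5)
    m, f = _signed_pair(t1, pd)
    maps = ts.fit_qmaps(m, f, MPRAGE, FGATIR)
    assert maps.valid.all()
    assert np.max(np.abs(maps.t1 - t1) / t1) < 1e-6
    assert np.max(np.abs(maps.pd - pd) / pd) < 1e-6
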
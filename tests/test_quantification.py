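"""Recovery-coefficient calibration, ROI background subtraction, hybrid
planar/SPECT tumour quantification and the two-compartment marrow model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnedose.constants import LU177
from tnedose.dose_rate import concentration_to_dose_rate
from tnedose.errors import FittingError, QuantificationError
from tnedose.quantification import (
    BMCompartmentSeries,
    RCModel,
    RoiRecord,
    SpectRecord,
    SphereMeasurement,
    background_correct,
    bm_dose_rate_series,
    fit_recovery_curve,
    recovery_coefficient,
    tumour_concentration_series,
)
from tnedose.synthetic import generate_patient, generate_phantom

DIAMETERS = (10.0, 12.0, 16.0, 20.0, 25.0, 31.0)


class TestRecoveryCoefficient:
    def test_half_recovery_at_scale_diameter(self, rc_truth):
        assert recovery_coefficient(rc_truth, rc_truth.a) == pytest.approx(0.5)

    def test_limit_to_one_for_large_objects(self, rc_truth):
        assert recovery_coefficient(rc_truth, 1e6 * rc_truth.a) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_hand_evaluated_value(self):
        # direct evaluation of 1/(1+(15/31)^2.5)
        expected = 1.0 / (1.0 + (15.0 / 31.0) ** 2.5)
        assert recovery_coefficient(RCModel(15.0, 2.5), 31.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rejects_nonpositive_diameter(self, rc_truth):
        with pytest.raises(ValueError):
            recovery_coefficient(rc_truth, 0.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(1.0, 100.0),
        b=st.floats(0.2, 8.0),
        d1=st.floats(0.5, 500.0),
        d2=st.floats(0.5, 500.0),
    )
    def test_strictly_monotone_in_diameter(self, a, b, d1, d2):
        model = RCModel(a=a, b=b)
        lo, hi = sorted((d1, d2))
        if hi - lo < 1e-9:
            return
        assert recovery_coefficient(model, lo) < recovery_coefficient(model, hi)
        assert 0.0 < recovery_coefficient(model, lo) < 1.0


class TestFitRecoveryCurve:
    def test_exact_sigmoid_data_recovers_parameters(self, rc_truth):
        meas = [
            SphereMeasurement(d, 1.0, float(recovery_coefficient(rc_truth, d)))
            for d in DIAMETERS
        ]
        fit = fit_recovery_curve(meas)
        assert fit.a == pytest.approx(rc_truth.a, rel=1e-6)
        assert fit.b == pytest.approx(rc_truth.b, rel=1e-6)

    def test_half_ratio_point_pins_scale_parameter(self):
        truth = RCModel(a=15.0, b=2.5)
        meas = [
            SphereMeasurement(d, 1.0, float(recovery_coefficient(truth, d)))
            for d in (15.0, 25.0, 31.0)
        ]
        fit = fit_recovery_curve(meas)
        # the 0.5-ratio measurement at d=15 mm sits exactly on RC(a)=1/2
        assert fit.a == pytest.approx(15.0, rel=1e-6)

    def test_noisy_ratios_recover_parameters_in_median(self, rc_truth):
        a_hat, b_hat = [], []
        for seed in range(100):
            meas = generate_phantom(DIAMETERS, rc_truth, noise_cv=0.03, seed=seed)
            fit = fit_recovery_curve(meas)
            a_hat.append(fit.a)
            b_hat.append(fit.b)
        assert np.median(a_hat) == pytest.approx(rc_truth.a, rel=0.10)
        assert np.median(b_hat) == pytest.approx(rc_truth.b, rel=0.10)

    def test_degenerate_inputs_raise(self):
        one = [SphereMeasurement(10.0, 1.0, 0.4)]
        with pytest.raises(FittingError):
            fit_recovery_curve(one)
        flat = [SphereMeasurement(d, 1.0, 0.7) for d in DIAMETERS]
        with pytest.raises(FittingError):
            fit_recovery_curve(flat)


class TestBackgroundCorrect:
    @pytest.mark.parametrize(
        "tum, bg, size_tu, size_bg, expected",
        [
            (10.0, 2.0, 100.0, 100.0, 8.0),   # equal sizes: plain subtraction
            (10.0, 2.0, 50.0, 100.0, 9.0),    # tumour ROI half the size
        ],
    )
    def test_size_adjusted_subtraction(self, tum, bg, size_tu, size_bg, expected):
        rec = RoiRecord(24.0, tum, bg, size_tu, size_bg)
        assert background_correct(rec) == pytest.approx(expected)

    def test_negative_net_clamps_to_zero_with_warning(self):
        rec = RoiRecord(24.0, 1.0, 2.0, 100.0, 100.0)
        with pytest.warns(UserWarning):
            assert background_correct(rec) == 0.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            RoiRecord(24.0, 1.0, 1.0, 0.0, 100.0)


def _planar(net, bg=2.0, size_tu=100.0, size_bg=200.0):
    return tuple(
        RoiRecord(t, n + bg * size_tu / size_bg, bg, size_tu, size_bg)
        for t, n in net
    )


class TestTumourConcentrationSeries:
    def test_flat_shape_gives_flat_corrected_series(self, rc_truth):
        planar = _planar([(2.0, 5.0), (24.0, 5.0), (48.0, 5.0), (168.0, 5.0)])
        spect = SpectRecord(c_spect_24h=0.8, equivalent_diameter_mm=20.0)
        series = tumour_concentration_series(spect, planar, rc_truth)
        rcd = recovery_coefficient(rc_truth, 20.0)
        for _, c in series:
            assert c == pytest.approx(0.8 / rcd, rel=1e-12)

    def test_very_large_tumour_needs_no_correction(self, rc_truth):
        planar = _planar([(2.0, 5.0), (24.0, 5.0), (48.0, 5.0), (168.0, 5.0)])
        spect = SpectRecord(c_spect_24h=0.8, equivalent_diameter_mm=1e9)
        series = tumour_concentration_series(spect, planar, rc_truth)
        c24 = dict(series)[24.0]
        assert c24 == pytest.approx(0.8, rel=1e-6)

    def test_zero_noise_roundtrip_matches_ground_truth(self, zero_noise_config):
        patient = generate_patient(zero_noise_config, seed=11)
        rc = zero_noise_config.rc_truth()
        series = tumour_concentration_series(
            patient.spect_24h, patient.planar_series, rc
        )
        truth = patient.kinetics["tumour"]
        for t, c in series:
            expected = float(truth.dose_rate(t)) / LU177.gy_per_h_per_mbq_per_g
            assert c == pytest.approx(expected, rel=1e-9)

    def test_shape_invariant_to_common_rescaling(self, rc_truth):
        net = [(2.0, 3.0), (24.0, 5.0), (48.0, 4.0), (168.0, 1.0)]
        spect = SpectRecord(c_spect_24h=0.8, equivalent_diameter_mm=20.0)
        base = tumour_concentration_series(spect, _planar(net), rc_truth)
        scaled = tumour_concentration_series(
            spect,
            _planar([(t, 7.3 * n) for t, n in net], bg=0.0),
            rc_truth,
        )
        for (t1, c1), (t2, c2) in zip(base, scaled):
            assert t1 == t2
            assert c1 == pytest.approx(c2, rel=1e-12)

    def test_pve_multiply_compat_mode(self, rc_truth):
        planar = _planar([(24.0, 5.0), (48.0, 4.0), (72.0, 3.0), (168.0, 1.0)])
        spect = SpectRecord(c_spect_24h=0.8, equivalent_diameter_mm=20.0)
        rcd = recovery_coefficient(rc_truth, 20.0)
        series = tumour_concentration_series(
            spect, planar, rc_truth, pve_mode="multiply"
        )
        assert dict(series)[24.0] == pytest.approx(0.8 * rcd, rel=1e-12)

    def test_missing_24h_record_raises(self, rc_truth):
        planar = _planar([(2.0, 5.0), (48.0, 4.0)])
        spect = SpectRecord(c_spect_24h=0.8, equivalent_diameter_mm=20.0)
        with pytest.raises(QuantificationError):
            tumour_concentration_series(spect, planar, rc_truth)


class TestBoneMarrowDoseRate:
    def test_zero_activities_give_zero_series(self):
        bm = BMCompartmentSeries(
            samples=((2.0, 0.0, 0.0), (24.0, 0.0, 0.0)),
            m_low_g=1000.0, cf=3.2, s_bm_from_low=1e-6, s_bm_from_high=1e-5,
        )
        assert all(r == 0.0 for r in bm_dose_rate_series(bm).rate_gy_per_h)

    def test_self_dose_term_dimensional_oracle(self):
        # 1 MBq/g with E_e=147 keV/decay and unit CF: the same 0.0848 Gy/h
        # as the concentration->dose-rate conversion
        bm = BMCompartmentSeries(
            samples=((24.0, 1000.0, 0.0),),
            m_low_g=1000.0, cf=1.0, s_bm_from_low=0.0, s_bm_from_high=0.0,
        )
        rate = bm_dose_rate_series(bm).rate_gy_per_h[0]
        assert rate == pytest.approx(float(concentration_to_dose_rate(1.0)), rel=1e-12)
        assert rate == pytest.approx(0.0848, rel=2e-3)

    def test_linearity_in_activities(self):
        base = BMCompartmentSeries(
            samples=((2.0, 300.0, 60.0), (24.0, 200.0, 50.0)),
            m_low_g=5000.0, cf=3.2, s_bm_from_low=5e-6, s_bm_from_high=5e-5,
        )
        doubled = BMCompartmentSeries(
            samples=tuple((t, 2 * a, 2 * h) for t, a, h in base.samples),
            m_low_g=5000.0, cf=3.2, s_bm_from_low=5e-6, s_bm_from_high=5e-5,
        )
        r1 = np.asarray(bm_dose_rate_series(base).rate_gy_per_h)
        r2 = np.asarray(bm_dose_rate_series(doubled).rate_gy_per_h)
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            BMCompartmentSeries(
                samples=((2.0, -1.0, 0.0),), m_low_g=1000.0,
            )
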
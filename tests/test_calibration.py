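"""Inverse solves: passive-modulus fit, contraction fit, drying sweep."""

import numpy as np
import pytest
from scipy.optimize import brentq

from conescale import (
    CalibrationError,
    DryingPath,
    TissueState,
    bend_scale,
    drying_sweep,
    fit_contraction,
    fit_passive_modulus,
    predict_interval_angle,
    preset_curve,
    xi_from_rh,
)


class TestFitPassiveModulus:
    @pytest.mark.parametrize("e_true", [200.0, 650.0, 1500.0, 3000.0])
    def test_round_trip_recovers_forward_modulus(self, scale, e_true):
        gamma = bend_scale(scale, TissueState(37.0, e_true, -0.22)).gamma_deg
        res = fit_passive_modulus(scale, target_gamma_deg=gamma,
                                  bracket=(150.0, 4000.0))
        assert res.converged
        assert res.fitted_value == pytest.approx(e_true, rel=1e-6)

    def test_dry_state_calibration_magnitude(self, scale):
        """The dry-state angle pins the passive modulus near the reported value."""
        res = fit_passive_modulus(scale, target_gamma_deg=24.4)
        assert res.converged
        assert abs(res.residual_deg) <= 1e-4
        assert res.fitted_value == pytest.approx(1170.0, rel=0.40)

    def test_agrees_with_brentq_and_dense_grid_scan(self, scale):
        """Independent oracles: scipy brentq and a 2000-point sign-change scan."""
        target = 24.4

        def f(e):
            return bend_scale(scale, TissueState(37.0, e, -0.22)).gamma_deg - target

        res = fit_passive_modulus(scale, target_gamma_deg=target)
        ref = brentq(f, 100.0, 5000.0, xtol=1e-9)
        assert res.fitted_value == pytest.approx(ref, rel=1e-8)

        es = np.linspace(100.0, 5000.0, 2000)
        vals = np.array([f(e) for e in es])
        (idx,) = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
        assert len(idx) == 1
        lo, hi = es[idx[0]], es[idx[0] + 1]
        assert lo <= res.fitted_value <= hi

    def test_bad_bracket_refused_with_diagnostics(self, scale):
        with pytest.raises(CalibrationError, match="gamma"):
            fit_passive_modulus(scale, target_gamma_deg=24.4,
                                bracket=(2000.0, 5000.0))

    def test_result_within_bracket(self, scale):
        res = fit_passive_modulus(scale, target_gamma_deg=24.4)
        lo, hi = res.bracket
        assert lo <= res.fitted_value <= hi


class TestFitContraction:
    ENDPOINTS = ((180.0, 21.0), (800.0, 37.0))  # (E_passive, E_active) wet, dry

    def test_zero_target_gives_zero_increment(self, scale):
        res = fit_contraction(scale, 0.0, ((180.0, 21.0), (180.0, 21.0)),
                              bracket=(0.0, 0.22))
        assert res.converged
        assert res.fitted_value == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("d_true", [0.03, 0.09, 0.15])
    def test_round_trip_recovers_forward_increment(self, scale, d_true):
        eps_start = -0.02
        (ep_a, ea_a), (ep_b, ea_b) = self.ENDPOINTS
        ga = bend_scale(scale, TissueState(ea_a, ep_a, eps_start)).gamma_deg
        gb = bend_scale(scale, TissueState(ea_b, ep_b, eps_start - d_true)).gamma_deg
        res = fit_contraction(scale, gb - ga, self.ENDPOINTS, eps_start=eps_start)
        assert res.converged
        assert res.fitted_value == pytest.approx(d_true, rel=1e-6)

    def test_measured_interval_angle_gives_reported_contraction(self, scale):
        """A 12-degree 80 -> 30 % rh change needs roughly 11 % contraction."""
        path = DryingPath()
        curve = preset_curve("sclerenchyma_sim")
        eps_start = path.active_strain(xi_from_rh(path, curve, 80.0))
        res = fit_contraction(scale, 12.0, self.ENDPOINTS, eps_start=eps_start)
        assert res.converged
        assert 100 * res.fitted_value == pytest.approx(11.0, abs=4.0)

    def test_unreachable_target_refused(self, scale):
        with pytest.raises(CalibrationError):
            fit_contraction(scale, 80.0, self.ENDPOINTS, bracket=(0.0, 0.05))


@pytest.fixture(scope="module")
def calibrated_path(scale):
    fit = fit_passive_modulus(scale, target_gamma_deg=24.4)
    return DryingPath().with_dry_modulus(fit.fitted_value)


class TestDryingSweep:
    def test_wet_reference_row_is_zero(self, scale, calibrated_path):
        tab = drying_sweep(scale, calibrated_path, 11)
        assert tab.loc[0, "xi"] == 0.0
        assert tab.loc[0, "gamma_deg"] == pytest.approx(0.0, abs=1e-12)

    def test_dry_row_reaches_calibration_target(self, scale, calibrated_path):
        tab = drying_sweep(scale, calibrated_path, 11)
        assert tab.iloc[-1]["gamma_deg"] == pytest.approx(24.4, abs=1e-3)

    def test_gamma_monotone_along_drying(self, scale, calibrated_path):
        tab = drying_sweep(scale, calibrated_path, 41)
        assert np.all(np.diff(tab["gamma_deg"]) >= 0)

    def test_columns_and_modulus_course(self, scale, calibrated_path):
        tab = drying_sweep(scale, calibrated_path, 11)
        assert list(tab.columns) == ["xi", "rh_percent", "E_passive_MPa",
                                     "eps_active", "gamma_deg"]
        assert np.all(np.diff(tab["E_passive_MPa"]) > 0)
        assert np.all(np.diff(tab["eps_active"]) < 0)

    def test_interval_additivity_along_path(self, scale, calibrated_path):
        """Angles are a state function: consecutive intervals sum exactly."""
        pred_full = predict_interval_angle(scale, calibrated_path, 80.0, 30.0)
        mid = 55.0
        a = predict_interval_angle(scale, calibrated_path, 80.0, mid)
        b = predict_interval_angle(scale, calibrated_path, mid, 30.0)
        assert a.gamma_deg + b.gamma_deg == pytest.approx(pred_full.gamma_deg,
                                                          rel=1e-12)


class TestIntervalPrediction:
    def test_same_humidity_gives_zero(self, scale, drying_path):
        pred = predict_interval_angle(scale, drying_path, 60.0, 60.0)
        assert pred.gamma_deg == 0.0
        assert pred.modulus_change_mpa == 0.0

    def test_modulus_difference_over_drying_interval(self, scale, drying_path):
        """Drying from 80 to 30 % rh stiffens the passive layer by 620 MPa."""
        pred = predict_interval_angle(scale, drying_path, 80.0, 30.0)
        assert pred.modulus_change_mpa == pytest.approx(620.0, abs=1e-12)

    def test_calibrated_interval_angle_near_measured(self, scale):
        fit = fit_passive_modulus(scale, target_gamma_deg=24.4)
        path = DryingPath().with_dry_modulus(fit.fitted_value)
        pred = predict_interval_angle(scale, path, 80.0, 30.0)
        assert pred.gamma_deg == pytest.approx(12.0, abs=4.0)

    def test_rh_outside_range_rejected(self, scale, drying_path):
        from conescale import DomainError

        with pytest.raises(DomainError):
            predict_interval_angle(scale, drying_path, -5.0, 30.0)
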
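"""Eigenstrain section mechanics and the bending forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from conescale import (
    BendingZone,
    DomainError,
    GeometryError,
    Layer,
    ScaleModel,
    SectionState,
    TissueState,
    angular_change,
    bend_scale,
    bilayer_section,
    section_response,
    timoshenko_curvature,
)


def two_layer(t1, t2, e1, e2, eps1, eps2, width=1.0):
    """Layer 1 above the interface, layer 2 below (the bilayer convention)."""
    return SectionState(layers=(
        Layer(t2, width, e2, eps2, -t2 / 2.0),
        Layer(t1, width, e1, eps1, +t1 / 2.0),
    ))


class TestSectionResponse:
    def test_uniform_eigenstrain_gives_zero_curvature(self):
        state = two_layer(0.6, 0.8, 1170.0, 37.0, -0.1, -0.1)
        resp = section_response(state)
        assert resp.kappa == pytest.approx(0.0, abs=1e-15)
        assert resp.eps0 == pytest.approx(-0.1)

    def test_zero_eigenstrains_give_zero_response(self):
        resp = section_response(two_layer(0.6, 0.8, 1170.0, 37.0, 0.0, 0.0))
        assert resp.eps0 == 0.0 and resp.kappa == 0.0

    def test_symmetric_bimetal_closed_form(self):
        # equal layers: kappa = 1.5 * delta_eps / h
        t, e, de = 1.0, 100.0, 0.1
        resp = section_response(two_layer(t, t, e, e, de, 0.0))
        assert resp.kappa == pytest.approx(1.5 * de / (2 * t), rel=1e-12)

    def test_linearity_in_eigenstrain_difference(self):
        base = section_response(two_layer(0.6, 0.8, 1170.0, 37.0, 0.0, -0.22)).kappa
        half = section_response(two_layer(0.6, 0.8, 1170.0, 37.0, 0.0, -0.11)).kappa
        double = section_response(two_layer(0.6, 0.8, 1170.0, 37.0, 0.0, -0.44)).kappa
        assert half == pytest.approx(base / 2, rel=1e-12)
        assert double == pytest.approx(base * 2, rel=1e-12)

    def test_frame_invariance_of_curvature(self):
        """Shifting the reference axis must not change the curvature."""
        for shift in (-0.7, 0.33, 2.0):
            plain = two_layer(0.6, 0.8, 1170.0, 37.0, 0.0, -0.22)
            shifted = SectionState(layers=tuple(
                Layer(l.thickness, l.width, l.modulus, l.eigenstrain,
                      l.z_center + shift)
                for l in plain.layers
            ))
            k0 = section_response(plain).kappa
            k1 = section_response(shifted).kappa
            assert k1 == pytest.approx(k0, rel=1e-9)

    def test_gap_between_layers_rejected(self):
        state = SectionState(layers=(
            Layer(0.8, 1.0, 37.0, 0.0, -0.5),
            Layer(0.6, 1.0, 1170.0, 0.0, +0.5),  # 0.1 mm gap at the interface
        ))
        with pytest.raises(GeometryError):
            section_response(state)

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(GeometryError):
            section_response(two_layer(0.6, 0.8, -5.0, 37.0, 0.0, -0.1))


class TestTimoshenkoOracle:
    def test_symmetric_strip(self):
        assert timoshenko_curvature(1.0, 1.0, 50.0, 50.0, 0.1) == pytest.approx(
            1.5 * 0.1 / 2.0
        )

    def test_zero_mismatch(self):
        assert timoshenko_curvature(0.6, 0.8, 1170.0, 37.0, 0.0) == 0.0

    def test_sign_follows_mismatch(self):
        up = timoshenko_curvature(0.6, 0.8, 1170.0, 37.0, 0.22)
        down = timoshenko_curvature(0.6, 0.8, 1170.0, 37.0, -0.22)
        assert up > 0 > down
        assert up == pytest.approx(-down)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            timoshenko_curvature(0.0, 0.8, 100.0, 37.0, 0.1)
        with pytest.raises(DomainError):
            timoshenko_curvature(0.6, 0.8, 100.0, -1.0, 0.1)

    def test_bending_zone_cross_section_matches_general_solver(self):
        """Dry-state start cross-section: closed form vs 2x2 solve."""
        kappa_cf = timoshenko_curvature(0.6, 0.8, 1170.0, 37.0, 0.22)
        resp = section_response(two_layer(0.6, 0.8, 1170.0, 37.0, 0.0, -0.22))
        assert resp.kappa == pytest.approx(kappa_cf, rel=1e-10)

    @settings(derandomize=True, max_examples=300)
    @given(
        t1=st.floats(min_value=0.05, max_value=5.0),
        t2=st.floats(min_value=0.05, max_value=5.0),
        e1=st.floats(min_value=1.0, max_value=5000.0),
        e2=st.floats(min_value=1.0, max_value=5000.0),
        de=st.floats(min_value=-0.5, max_value=0.5),
        width=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_oracle_equivalence_random_sections(self, t1, t2, e1, e2, de, width):
        """General eigenstrain solver == bimetal closed form, any bilayer."""
        kappa_cf = timoshenko_curvature(t1, t2, e1, e2, de)
        resp = section_response(two_layer(t1, t2, e1, e2, 0.0, -de, width=width))
        assert resp.kappa == pytest.approx(kappa_cf, rel=1e-10, abs=1e-14)


class TestBendScale:
    def test_prismatic_zone_angle_is_kappa_times_length(self):
        zone = BendingZone(length_mm=4.0, w_start=2.0, w_end=2.0,
                           n_stations=21)
        zone = BendingZone(length_mm=4.0, w_start=2.0, w_end=2.0,
                           active=zone.active.__class__("active", 0.8, 0.8),
                           passive=zone.passive.__class__("passive", 0.6, 0.6),
                           n_stations=21)
        model = ScaleModel(zone=zone)
        state = TissueState(e_active=37.0, e_passive=1170.0, eps_active=-0.22)
        res = bend_scale(model, state)
        kappa = timoshenko_curvature(0.6, 0.8, 1170.0, 37.0, 0.22)
        assert res.gamma_deg == pytest.approx(np.degrees(kappa * 4.0), rel=1e-12)

    def test_theta_starts_at_zero_and_gamma_matches_theta_end(self, scale):
        res = bend_scale(scale, TissueState(37.0, 1170.0, -0.22))
        assert res.theta_field[0] == 0.0
        assert res.gamma_deg == pytest.approx(np.degrees(res.theta_field[-1]))
        assert np.allclose(res.centerline[0], [0.0, 0.0])

    def test_drying_bends_to_positive_angles(self, scale):
        res = bend_scale(scale, TissueState(37.0, 1170.0, -0.22))
        assert res.gamma_deg > 0

    def test_orientation_flag_flips_sign(self, scale):
        flipped = ScaleModel(zone=scale.zone, lever_mm=scale.lever_mm,
                             active_below=False)
        g = bend_scale(scale, TissueState(37.0, 1170.0, -0.22)).gamma_deg
        gf = bend_scale(flipped, TissueState(37.0, 1170.0, -0.22)).gamma_deg
        assert gf == pytest.approx(-g)

    def test_quadrature_convergence_on_station_doubling(self, scale):
        state = TissueState(37.0, 1170.0, -0.22)
        g1 = bend_scale(scale, state).gamma_deg
        doubled = ScaleModel(
            zone=BendingZone(
                length_mm=scale.zone.length_mm,
                w_start=scale.zone.w_start, w_end=scale.zone.w_end,
                active=scale.zone.active, passive=scale.zone.passive,
                n_stations=2 * scale.zone.n_stations - 1,
            ),
            lever_mm=scale.lever_mm,
        )
        g2 = bend_scale(doubled, state).gamma_deg
        assert abs(g2 - g1) / abs(g1) < 1e-6

    def test_gamma_strictly_decreasing_in_passive_modulus(self, scale):
        """Stiff branch (E_passive/E_active >= 4): unique inverse solve."""
        es = np.linspace(4 * 37.0, 5000.0, 25)
        gammas = [bend_scale(scale, TissueState(37.0, e, -0.22)).gamma_deg
                  for e in es]
        assert np.all(np.diff(gammas) < 0)

    def test_invalid_geometry_rejected(self):
        model = ScaleModel(zone=BendingZone(w_end=-1.0))
        with pytest.raises(GeometryError):
            bend_scale(model, TissueState(37.0, 1170.0, -0.22))

    def test_tip_position_matches_elastica_integration(self, scale):
        """Finite-rotation trapezoid centerline vs ODE elastica oracle."""
        state = TissueState(37.0, 1170.0, -0.22)
        res = bend_scale(scale, state)
        s = res.stations
        kappa = res.kappa_field

        def rhs(t, y):
            k = np.interp(t, s, kappa)
            return [np.cos(y[2]), np.sin(y[2]), k]

        sol = solve_ivp(rhs, (0, s[-1]), [0.0, 0.0, 0.0], rtol=1e-10,
                        atol=1e-12, dense_output=True)
        x, y, theta = sol.y[:, -1]
        zone_end = res.centerline[-2]
        assert zone_end[0] == pytest.approx(x, abs=5e-5)
        assert zone_end[1] == pytest.approx(y, abs=5e-5)
        assert np.degrees(theta) == pytest.approx(res.gamma_deg, rel=1e-5)

    def test_lever_extends_tip_along_final_tangent(self, scale):
        res = bend_scale(scale, TissueState(37.0, 1170.0, -0.22))
        direction = res.centerline[-1] - res.centerline[-2]
        theta_end = res.theta_field[-1]
        assert np.hypot(*direction) == pytest.approx(scale.lever_mm)
        assert np.arctan2(direction[1], direction[0]) == pytest.approx(theta_end)


class TestAngularChange:
    def test_identical_states_give_zero(self, scale):
        s = TissueState(30.0, 500.0, -0.1)
        assert angular_change(scale, s, s) == 0.0

    def test_antisymmetric_under_swap(self, scale):
        a = TissueState(21.0, 180.0, -0.02)
        b = TissueState(37.0, 800.0, -0.14)
        assert angular_change(scale, a, b) == pytest.approx(
            -angular_change(scale, b, a)
        )
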
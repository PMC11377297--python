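"""Worm-like-chain force law, V-tether geometry and the two-DNA system."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringrupture.polymer import (
    KBT_ROOM_PN_NM,
    LAMBDA_DNA,
    OverstretchError,
    WLCParams,
    solve_two_dna,
    tether_geometry,
    two_dna_residuals,
    wlc_force,
)


class TestWlcForce:
    def test_zero_extension_gives_zero_force(self):
        assert wlc_force(LAMBDA_DNA, 0.0) == pytest.approx(0.0)

    def test_half_extension_matches_closed_form(self):
        # (kBT/P) * (1/(4*0.25) - 1/4 + 1/2) = 0.08228 * 1.25
        f = wlc_force(WLCParams(50.0, 16320.0), 8160.0, 4.114)
        assert f == pytest.approx(0.10285, rel=1e-4)

    def test_contour_length_is_a_domain_error(self):
        with pytest.raises(OverstretchError):
            wlc_force(LAMBDA_DNA, LAMBDA_DNA.contour_length_nm)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            wlc_force(LAMBDA_DNA, -1.0)

    @given(
        p=st.floats(1.0, 200.0),
        l0=st.floats(100.0, 50_000.0),
        frac=st.floats(0.01, 0.95),
        dfrac=st.floats(0.001, 0.04),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_length(self, p, l0, frac, dfrac):
        wlc = WLCParams(p, l0)
        a, b = frac * l0, min((frac + dfrac) * l0, 0.97 * l0)
        assert wlc_force(wlc, b) > wlc_force(wlc, a)

    def test_force_scales_linearly_with_thermal_energy(self):
        lengths = np.linspace(0.0, 0.9, 7) * LAMBDA_DNA.contour_length_nm
        f1 = wlc_force(LAMBDA_DNA, lengths, 4.114)
        f2 = wlc_force(LAMBDA_DNA, lengths, 8.228)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WLCParams(-1.0, 100.0)
        with pytest.raises(ValueError):
            WLCParams(50.0, 0.0)


class TestTetherGeometry:
    def test_slack_symmetric_case(self):
        g = tether_geometry(8800.0, 0.0)
        assert g.half_angle_rad == 0.0
        assert g.dna_length_nm == pytest.approx(8800.0)
        assert g.ring_force_pn == 0.0

    def test_stretched_case_matches_hand_calculation(self):
        g = tether_geometry(8800.0, 4000.0, WLCParams(50.0, 16320.0), 4.114)
        assert g.dna_length_nm == pytest.approx(11892.9, rel=1e-4)
        assert np.sin(g.half_angle_rad) == pytest.approx(0.6727, rel=1e-3)
        assert g.dna_tension_pn == pytest.approx(0.319, rel=2e-3)
        assert g.ring_force_pn == pytest.approx(0.429, rel=2e-3)

    def test_mirror_symmetry_in_displacement(self):
        a = tether_geometry(8800.0, 3000.0)
        b = tether_geometry(8800.0, -3000.0)
        assert a.ring_force_pn == b.ring_force_pn

    def test_ring_force_strictly_increasing_in_displacement(self):
        xs = np.linspace(100.0, 6500.0, 40)
        forces = [tether_geometry(8800.0, x).ring_force_pn for x in xs]
        assert np.all(np.diff(forces) > 0)

    def test_overstretch_raises(self):
        with pytest.raises(OverstretchError):
            tether_geometry(8800.0, 8000.0)  # L = 17.9 um > 16.32 um contour


class TestTwoDna:
    def test_slack_configuration(self):
        s = solve_two_dna(8800.0, 0.0)
        assert s.f1_pn == 0.0
        assert s.l1_nm == 0.0
        assert s.half_angle_rad == 0.0
        assert s.l2_nm == pytest.approx(8800.0)

    @pytest.mark.parametrize("x_nm", [500.0, 2000.0, 5000.0, 9000.0, 14000.0])
    def test_residuals_below_tolerance(self, x_nm):
        """The returned state satisfies all five equations of the system."""
        s = solve_two_dna(8800.0, x_nm, tol=1e-8)
        res = two_dna_residuals(s, 8800.0, x_nm)
        assert np.max(np.abs(res)) <= 1e-8
        assert s.residual_norm <= 1e-8

    def test_degenerate_limit_recovers_single_tether(self):
        """As the bead-proximal contour shrinks, F1 -> single-tether ring force."""
        tiny = WLCParams(50.0, 5.0)
        x = 5000.0
        s = solve_two_dna(8800.0, x, wlc1=tiny)
        g = tether_geometry(8800.0, x)
        assert s.f1_pn == pytest.approx(g.ring_force_pn, rel=0.01)

    def test_solution_continuous_in_displacement(self):
        xs = np.linspace(3000.0, 12000.0, 60)
        f1 = np.array([solve_two_dna(8800.0, x).f1_pn for x in xs])
        # no jumps: increments bounded and monotone force growth
        assert np.all(np.diff(f1) > 0)
        assert np.max(np.diff(f1)) < 1.0

    def test_overstretch_both_chains_raises(self):
        short = WLCParams(50.0, 1500.0)
        with pytest.raises(OverstretchError):
            solve_two_dna(8800.0, 16000.0, wlc1=short, wlc2=WLCParams(50.0, 9000.0))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            solve_two_dna(-1.0, 100.0)
        with pytest.raises(ValueError):
            solve_two_dna(8800.0, -5.0)
        with pytest.raises(ValueError):
            solve_two_dna(8800.0, 100.0, tol=0.0)
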
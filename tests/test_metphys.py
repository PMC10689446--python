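"""Closed-form meteorological and ecophysiological formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peatvpd import metphys
from peatvpd.exceptions import DegenerateInputError, InvalidInputError


class TestSaturationVaporPressure:
    @pytest.mark.parametrize("ta, expected, tol", [
        (0.0, 6.11, 1e-12),        # exp(0) = 1 pins the coefficient
        (25.0, 25.979, 1e-3),
        (-10.0, 3.1709, 1e-4),
    ])
    def test_known_values(self, ta, expected, tol):
        assert metphys.svp(ta) == pytest.approx(expected, abs=tol)

    def test_strictly_increasing(self):
        ta = np.linspace(-40, 40, 500)
        assert np.all(np.diff(metphys.svp(ta)) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            metphys.svp(np.nan)


class TestVpd:
    def test_saturation_gives_zero(self):
        assert metphys.vpd_from_rh(17.3, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_humidity_at_zero_degrees(self):
        assert metphys.vpd_from_rh(0.0, 50.0) == pytest.approx(3.055, abs=1e-12)

    def test_rh_out_of_range_rejected(self):
        for rh in (-1.0, 100.5):
            with pytest.raises(InvalidInputError):
                metphys.vpd_from_rh(10.0, rh)

    def test_decreasing_in_rh(self):
        rh = np.linspace(0, 100, 200)
        assert np.all(np.diff(metphys.vpd_from_rh(12.0, rh)) < 0)

    def test_avp_forms(self):
        assert metphys.vpd_from_avp(25.0, 10.0) == pytest.approx(
            metphys.svp(25.0) - 10.0, abs=1e-12)
        assert metphys.vpd_from_avp(5.0, metphys.svp(5.0)) == pytest.approx(0.0)
        assert metphys.vpd_from_avp(5.0, 0.0) == pytest.approx(metphys.svp(5.0))

    def test_supersaturation_retained_not_clipped(self):
        out = metphys.vpd_from_avp(0.0, 10.0)   # avp > svp(0) = 6.11
        assert out < 0

    def test_rh_and_avp_routes_identical_on_grid(self):
        """The two VPD definitions agree to machine precision: the RH route
        equals the AVP route evaluated at avp = svp*rh/100."""
        ta, rh = np.meshgrid(np.linspace(-35, 40, 100), np.linspace(0, 100, 100))
        lhs = metphys.vpd_from_rh(ta, rh)
        rhs = metphys.vpd_from_avp(ta, metphys.svp(ta) * rh / 100.0)
        assert np.allclose(lhs, rhs, rtol=0, atol=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(ta=st.floats(-40, 45), rh=st.floats(0, 100))
    def test_rh_avp_identity_property(self, ta, rh):
        lhs = metphys.vpd_from_rh(ta, rh)
        rhs = metphys.vpd_from_avp(ta, metphys.svp(ta) * rh / 100.0)
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestAerodynamicResistance:
    def test_worked_value(self):
        # k*ws/u* = 4: 3*0.16 / ln(e^4 - 0.7)^2
        assert metphys.aerodynamic_resistance(3.0, 0.3) == pytest.approx(0.030194, abs=1e-5)

    def test_joint_scaling(self):
        """Scaling ws and u* together leaves the log term unchanged, so the
        resistance scales with ws."""
        base = metphys.aerodynamic_resistance(3.0, 0.3)
        assert metphys.aerodynamic_resistance(12.0, 1.2) == pytest.approx(4 * base, rel=1e-12)

    def test_degenerate_log_term(self):
        # k*ws/u* = ln(1.7) makes the squared log vanish
        with pytest.raises(DegenerateInputError):
            metphys.aerodynamic_resistance(1.0, 0.4 / np.log(1.7))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            metphys.aerodynamic_resistance(-1.0, 0.3)
        with pytest.raises(InvalidInputError):
            metphys.aerodynamic_resistance(3.0, 0.0)


class TestCanopyConductance:
    def test_forward_inverse_round_trip(self, rng):
        """Inverting the forward Penman–Monteith flux recovers the known
        conductance on 1,000 random parameter draws."""
        n = 1000
        gc = rng.uniform(1.0, 20.0, n)
        h = rng.uniform(10.0, 150.0, n)
        vpd = rng.uniform(1.0, 25.0, n)
        ws = rng.uniform(0.5, 8.0, n)
        ustar = rng.uniform(0.1, 1.0, n)
        ta = rng.uniform(-5.0, 30.0, n)
        le = metphys.penman_monteith_le(gc, h, vpd, ws, ustar, ta)
        rec = metphys.canopy_conductance(le, h, vpd, ws, ustar, ta)
        assert np.nanmax(np.abs(rec - gc) / gc) < 1e-8

    def test_bracket_cancellation(self):
        """When H = LE*gamma/delta the resistance term vanishes and Gc reduces
        to gamma*LE/(rho*cp*VPD) in m/s."""
        ta, vpd, ws, ustar, le = 15.0, 8.0, 3.0, 0.3, 100.0
        c = metphys.PhysConstants.from_met(ta)
        h = le * float(c.gamma) / float(c.delta)
        gc = metphys.canopy_conductance(le, h, vpd, ws, ustar, ta)
        expected = 1000.0 * float(c.gamma) * le / (float(c.rho) * c.cp * vpd * 100.0)
        assert gc == pytest.approx(expected, rel=1e-10)

    def test_monotone_decreasing_in_vpd(self):
        g1 = metphys.canopy_conductance(100.0, 60.0, 5.0, 3.0, 0.3, 15.0)
        g2 = metphys.canopy_conductance(100.0, 60.0, 10.0, 3.0, 0.3, 15.0)
        assert g2 < g1

    def test_nonphysical_masked(self):
        # negative LE (condensation) drives the bracketed term negative
        out = metphys.canopy_conductance(
            np.array([-50.0]), np.array([10.0]), np.array([10.0]),
            np.array([3.0]), np.array([0.3]), np.array([15.0]))
        assert np.isnan(out[0])


class TestEtAndUwue:
    def test_et_from_le(self):
        assert metphys.et_from_le(0.0) == 0.0
        assert metphys.et_from_le(244.0) == pytest.approx(1e-4)
        # literal printed-coefficient mode
        assert metphys.et_from_le(244.0, coefficient=2.44) == pytest.approx(100.0)

    def test_et_linearity(self, rng):
        le = rng.uniform(0, 300, 50)
        assert np.allclose(metphys.et_from_le(3 * le), 3 * np.asarray(metphys.et_from_le(le)))

    @pytest.mark.parametrize("gpp, vpd, et, expected", [
        (2.0, 1.0, 1.0, 2.0),
        (3.0, 0.25, 1.5, 1.0),
        (5.0, 0.0, 2.0, 0.0),
    ])
    def test_uwue_values(self, gpp, vpd, et, expected):
        assert metphys.uwue(gpp, vpd, et) == pytest.approx(expected)

    def test_uwue_scale_invariance(self, rng):
        gpp, vpd, et = rng.uniform(1, 10, 3)
        for a in (0.5, 2.0, 7.3):
            assert metphys.uwue(a * gpp, vpd, a * et) == pytest.approx(
                metphys.uwue(gpp, vpd, et), rel=1e-12)

    def test_uwue_nonpositive_et_missing(self):
        assert np.isnan(metphys.uwue(2.0, 1.0, 0.0))


class TestGrowingSeason:
    def test_strict_zero_boundary(self):
        mask = metphys.growing_season_mask(np.array([-5.0, 0.0, 1.0]))
        assert mask.tolist() == [False, False, True]

    def test_all_positive(self):
        assert metphys.growing_season_mask(np.full(12, 5.0)).all()

    def test_climatology_matches_per_month_brute_force(self, rng):
        import pandas as pd
        idx = pd.date_range("2000-01-01", periods=36, freq="MS")
        ta = pd.Series(10 * np.sin(2 * np.pi * (idx.month - 4) / 12)
                       + rng.normal(0, 2, 36), index=idx)
        mask = metphys.growing_season_mask(ta, climatology=True)
        for m in range(1, 13):
            expected = ta[idx.month == m].mean() > 0
            assert (mask[idx.month == m] == expected).all()

    def test_non_monthly_rejected(self):
        import pandas as pd
        idx = pd.date_range("2000-01-01", periods=10, freq="D")
        with pytest.raises(InvalidInputError):
            metphys.growing_season_mask(pd.Series(np.ones(10), index=idx))
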
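"""The twelve thermal indices: oracle equivalence and hand-arithmetic checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermidx import indices as idx
from thermidx.meteo import vapor_pressure_from_dewpoint
from thermidx.utci_reference import utci_approx_reference


def factorial_grid(n=5):
    """n^4 factorial grid spanning the polynomial validity region."""
    ta = np.linspace(-40.0, 45.0, n)
    va = np.linspace(0.5, 17.0, n)
    rh = np.linspace(10.0, 95.0, n)
    dmrt = np.linspace(-20.0, 60.0, n)
    TA, VA, RH, DM = np.meshgrid(ta, va, rh, dmrt, indexing="ij")
    # vapour pressure from RH at the air temperature, capped at the
    # polynomial's 50 hPa validity bound
    E = np.minimum(RH / 100.0 * vapor_pressure_from_dewpoint(TA + 273.15), 50.0)
    return TA.ravel(), VA.ravel(), E.ravel(), (TA + DM).ravel()


class TestUTCI:
    def test_matches_reference_on_factorial_grid(self):
        ta, va, e, mrt = factorial_grid(5)
        mine = idx.utci(ta, va, e, mrt)
        ref = np.array([utci_approx_reference(a, b, m, c)
                        for a, b, c, m in zip(ta, va, e, mrt)])
        assert np.max(np.abs(mine - ref)) <= 0.01

    def test_reference_environment_returns_air_temperature(self):
        # in the reference environment (MRT = Ta, va = 0.5 m/s, RH 50% or
        # e = 20 hPa above 29 C) the equivalent temperature is the air
        # temperature itself, up to the polynomial approximation error
        for ta in [0.0, 10.0, 20.0, 25.0, 29.0, 35.0, 40.0]:
            e = 0.5 * vapor_pressure_from_dewpoint(ta + 273.15) if ta <= 29 else 20.0
            assert idx.utci(ta, 0.5, e, ta) == pytest.approx(ta, abs=1.0)

    def test_radiant_heat_raises_utci_when_warm(self):
        assert idx.utci(30.0, 2.0, 20.0, 40.0) > idx.utci(30.0, 2.0, 20.0, 30.0)

    def test_wind_cools_in_cold(self):
        assert idx.utci(-10.0, 10.0, 2.0, -10.0) < idx.utci(-10.0, 1.0, 2.0, -10.0)

    def test_variant_lattice_exact(self):
        rng = np.random.default_rng(99)
        ta = rng.uniform(-40.0, 45.0, 10_000)
        e = rng.uniform(0.5, 45.0, 10_000)
        indoor = idx.utci_indoor(ta, e)
        shaded = idx.utci_outdoor_shaded(ta, np.full_like(ta, 0.5), e)
        full = idx.utci(ta, np.full_like(ta, 0.5), e, ta)
        np.testing.assert_array_equal(indoor, shaded)
        np.testing.assert_array_equal(shaded, full)

    def test_shaded_is_utci_with_mrt_equal_ta(self):
        assert idx.utci_outdoor_shaded(35.0, 5.0, 30.0) == idx.utci(35.0, 5.0, 30.0, 35.0)

    def test_qc_mask_records_clamps(self):
        qc = idx.QCMask()
        idx.utci(np.array([60.0, 20.0]), np.array([0.1, 2.0]),
                 np.array([10.0, 10.0]), np.array([60.0, 20.0]), qc=qc)
        assert qc.n_clamped == 1  # first element clamped (Ta and va), second clean
        assert qc.events["Ta"] == 1 and qc.events["Va10"] == 1

    def test_finite_on_validity_grid(self):
        ta, va, e, mrt = factorial_grid(5)
        assert np.all(np.isfinite(idx.utci(ta, va, e, mrt)))


class TestApparentTemperature:
    def test_hand_value(self):
        assert idx.apparent_temperature(25.0, 20.0, 0.0) == pytest.approx(27.6)

    @settings(deadline=None)
    @given(st.floats(-20, 45), st.floats(0, 15))
    def test_neutral_locus(self, ta, va):
        e = (0.7 * va + 4.0) / 0.33
        assert idx.apparent_temperature(ta, e, va) == pytest.approx(ta, abs=1e-9)

    def test_wind_slope(self):
        a = idx.apparent_temperature(25.0, 20.0, 3.0)
        b = idx.apparent_temperature(25.0, 20.0, 4.0)
        assert b - a == pytest.approx(-0.7)


class TestESI:
    def test_hand_value(self):
        assert idx.environment_stress_index(30.0, 50.0, 500.0) == pytest.approx(
            26.49985403, abs=1e-6)

    def test_zero_case(self):
        assert idx.environment_stress_index(0.0, 0.0, 0.0) == pytest.approx(-0.73)

    def test_increasing_in_radiation(self):
        sr = np.linspace(0.0, 1000.0, 200)
        esi = idx.environment_stress_index(30.0, 50.0, sr)
        assert np.all(np.diff(esi) > 0)


class TestHeatIndex:
    def test_simple_branch_below_threshold(self):
        # 79 F, 50% -> simple formula 78.95 F, stays below the 80 F switch
        ta_c = (79.0 - 32.0) / 1.8
        assert idx.heat_index(ta_c, 50.0) == pytest.approx((78.95 - 32.0) / 1.8, abs=1e-6)

    def test_rothfusz_branch(self):
        # oracle: direct evaluation of the regression at 90 F, 50% -> 94.597 F
        ta_c = (90.0 - 32.0) / 1.8
        assert idx.heat_index(ta_c, 50.0) == pytest.approx(34.77607844, abs=1e-6)

    def test_low_humidity_adjustment(self):
        # 95 F at RH 10%: adjustment (13-10)/4 * sqrt(17/17) = 0.75 F subtracted
        ta_c = (95.0 - 32.0) / 1.8
        assert idx.heat_index(ta_c, 10.0) == pytest.approx((89.4495873 - 32.0) / 1.8, abs=1e-6)

    def test_high_humidity_adjustment_window(self):
        # inside the window (RH > 85, 80-87 F) the correction is added
        ta_c = (84.0 - 32.0) / 1.8
        with_adj = idx.heat_index(ta_c, 90.0)
        T, RH = 84.0, 90.0
        roth = (-42.379 + 2.04901523 * T + 10.14333127 * RH - 0.22475541 * T * RH
                - 0.00683783 * T ** 2 - 0.05481717 * RH ** 2 + 0.00122874 * T ** 2 * RH
                + 0.00085282 * T * RH ** 2 - 0.00000199 * T ** 2 * RH ** 2)
        expected = roth + (RH - 85.0) / 10.0 * (87.0 - T) / 5.0
        assert with_adj == pytest.approx((expected - 32.0) / 1.8, abs=1e-9)


class TestHumidex:
    def test_identity_point(self):
        assert idx.humidex(22.5, 10.0) == pytest.approx(22.5)

    def test_hand_value(self):
        assert idx.humidex(30.0, 28.0) == pytest.approx(39.999, abs=1e-9)

    @settings(deadline=None)
    @given(st.floats(-30, 45), st.floats(0, 45))
    def test_slope_in_vapour_pressure(self, ta, e):
        assert idx.humidex(ta, e + 1.0) - idx.humidex(ta, e) == pytest.approx(0.5555, abs=1e-9)


class TestNET:
    def test_saturated_37_degrees_fixed_point(self):
        for va in [0.1, 1.0, 5.0]:
            assert idx.net_effective_temperature(37.0, 100.0, va) == pytest.approx(37.0)

    def test_hand_value(self):
        assert idx.net_effective_temperature(20.0, 50.0, 1.0) == pytest.approx(
            15.75049870, abs=1e-6)

    def test_wind_cools_below_37(self):
        va = np.linspace(0.1, 10.0, 100)
        for ta in [0.0, 15.0, 30.0]:
            net = idx.net_effective_temperature(ta, 50.0, va)
            assert np.all(np.diff(net) < 0)


class TestWBGT:
    def test_hand_value(self):
        assert idx.wbgt_simplified(30.0, 20.0) == pytest.approx(28.81)

    def test_intercept(self):
        assert idx.wbgt_simplified(0.0, 0.0) == pytest.approx(3.94)

    def test_linear_in_both(self):
        assert idx.wbgt_simplified(31.0, 20.0) - idx.wbgt_simplified(30.0, 20.0) == pytest.approx(0.567)
        assert idx.wbgt_simplified(30.0, 21.0) - idx.wbgt_simplified(30.0, 20.0) == pytest.approx(0.393)


class TestWBT:
    def test_hand_value(self):
        assert idx.wbt_stull(20.0, 50.0) == pytest.approx(13.69934197, abs=1e-6)

    def test_near_saturation_approaches_air_temperature(self):
        ta = np.linspace(-20.0, 50.0, 71)
        assert np.max(np.abs(idx.wbt_stull(ta, 99.0) - ta)) <= 1.0

    def test_never_much_above_air_temperature(self):
        # grid scan of the fit: the excess over Ta peaks at 2.41 C in the
        # cold/dry corner (an artifact of the regression) and stays below
        # 0.05 C for Ta >= 0
        ta, rh = np.meshgrid(np.linspace(-20.0, 50.0, 71), np.linspace(5.0, 99.0, 95))
        excess = idx.wbt_stull(ta, rh) - ta
        assert np.max(excess) <= 2.45
        assert np.max(excess[:, ta[0] >= 0.0]) <= 0.05

    def test_validity_flagging(self):
        qc = idx.QCMask()
        idx.wbt_stull(np.array([20.0, 60.0]), np.array([50.0, 50.0]), qc=qc)
        assert qc.events["wbt_validity"] == 1


class TestWCT:
    def test_hand_value(self):
        assert idx.wind_chill_temperature(-20.0, 30.0 / 3.6) == pytest.approx(
            -32.568044, abs=1e-4)

    def test_calm_limit(self):
        assert idx.wind_chill_temperature(-20.0, 0.0) == pytest.approx(
            13.12 + 0.6215 * -20.0)

    def test_wind_deepens_chill_when_cold(self):
        va = np.linspace(1.0, 20.0, 100)
        for ta in [-30.0, -10.0, 5.0]:
            wct = idx.wind_chill_temperature(ta, va)
            assert np.all(np.diff(wct) < 0)


def test_vectorization_matches_scalar_application():
    """Elementwise array evaluation equals per-element scalar calls."""
    rng = np.random.default_rng(17)
    n = 20
    ta = rng.uniform(-30.0, 45.0, n)
    e = rng.uniform(1.0, 40.0, n)
    rh = rng.uniform(5.0, 99.0, n)
    va = rng.uniform(0.5, 15.0, n)
    mrt = ta + rng.uniform(-20.0, 50.0, n)
    sr = rng.uniform(0.0, 900.0, n)
    cases = [
        (idx.utci, (ta, va, e, mrt)),
        (idx.utci_outdoor_shaded, (ta, va, e)),
        (idx.utci_indoor, (ta, e)),
        (idx.apparent_temperature, (ta, e, va)),
        (idx.environment_stress_index, (ta, rh, sr)),
        (idx.heat_index, (ta, rh)),
        (idx.humidex, (ta, e)),
        (idx.net_effective_temperature, (ta, rh, va)),
        (idx.wbgt_simplified, (ta, e)),
        (idx.wbt_stull, (ta, rh)),
        (idx.wind_chill_temperature, (ta, va)),
    ]
    for fn, args in cases:
        vec = fn(*args)
        scal = np.array([fn(*[a[i] for a in args]) for i in range(n)])
        np.testing.assert_allclose(vec, scal, atol=1e-9, err_msg=fn.__name__)
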
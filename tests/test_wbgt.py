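"""The Tmax/VPDmax -> RH -> heat index -> indoor WBGT chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazardheat.wbgt import (
    WbgtTransformParams,
    daily_wbgt_series,
    heat_index,
    relative_humidity_from_vpd,
    saturation_vapor_pressure,
    wbgt_from_heat_index,
)

from _nws_oracle import magnus_es_hpa, nws_heat_index_f


def c_to_f(t):
    return t * 9 / 5 + 32


class TestSaturationVaporPressure:
    @pytest.mark.parametrize("t, expected", [(0.0, 6.112), (20.0, 23.4)])
    def test_magnus_reference_values(self, t, expected):
        assert saturation_vapor_pressure(t) == pytest.approx(expected, abs=0.05)
        assert saturation_vapor_pressure(t) == pytest.approx(magnus_es_hpa(t))

    def test_strictly_increasing(self):
        es = saturation_vapor_pressure(np.array([10.0, 20.0, 30.0]))
        assert es[2] > es[1] > es[0] > 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="physical range"):
            saturation_vapor_pressure(-70.0)
        with pytest.raises(ValueError):
            saturation_vapor_pressure(np.array([20.0, 61.0]))

    def test_nan_propagates_as_missing(self):
        assert np.isnan(saturation_vapor_pressure(np.array([np.nan]))[0])


class TestRelativeHumidityFromVpd:
    def test_zero_deficit_is_saturation(self):
        assert relative_humidity_from_vpd(25.0, 0.0) == 100.0

    def test_full_deficit_is_zero(self):
        es = saturation_vapor_pressure(30.0)
        assert relative_humidity_from_vpd(30.0, es) == pytest.approx(0.0)

    def test_half_deficit_is_fifty(self):
        es = magnus_es_hpa(28.0)  # independent e_s evaluation
        assert relative_humidity_from_vpd(28.0, 0.5 * es) == pytest.approx(50.0)

    def test_negative_vpd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            relative_humidity_from_vpd(20.0, -1.0)

    @given(
        t=st.floats(-30.0, 50.0),
        vpd=st.floats(0.0, 150.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_property(self, t, vpd):
        rh = relative_humidity_from_vpd(t, vpd)
        assert 0.0 <= rh <= 100.0


class TestHeatIndex:
    def test_matches_oracle_at_ninety_f_fifty_pct(self):
        # 90 degF / 50 % RH: the full Rothfusz branch
        ours_f = c_to_f(heat_index(32.22, 50.0))
        assert abs(ours_f - nws_heat_index_f(c_to_f(32.22), 50.0)) < 0.1

    def test_low_branch_below_eighty_f(self):
        ours_f = c_to_f(heat_index(15.0, 50.0))
        assert ours_f == pytest.approx(nws_heat_index_f(c_to_f(15.0), 50.0))
        assert ours_f < 80.0

    def test_zero_rh_low_temp_is_simple_formula(self):
        t_f = c_to_f(10.0)
        expected = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2)
        assert c_to_f(heat_index(10.0, 0.0)) == pytest.approx(expected)

    def test_oracle_equivalence_grid(self):
        """Whole-domain agreement with the independent transcription, <0.1 degF."""
        for t_c in np.arange(26.0, 46.1, 1.0):
            for rh in np.arange(0.0, 100.1, 5.0):
                ours = c_to_f(heat_index(float(t_c), float(rh)))
                ref = nws_heat_index_f(c_to_f(float(t_c)), float(rh))
                assert abs(ours - ref) < 0.1, (t_c, rh)

    def test_vectorized_matches_scalar(self):
        t = np.array([20.0, 30.0, 38.0, 44.0])
        rh = np.array([10.0, 55.0, 90.0, 5.0])
        vec = heat_index(t, rh)
        for i in range(len(t)):
            assert vec[i] == pytest.approx(heat_index(float(t[i]), float(rh[i])))

    def test_invalid_rh_rejected(self):
        with pytest.raises(ValueError, match="rh"):
            heat_index(30.0, 101.0)
        with pytest.raises(ValueError):
            heat_index(30.0, -0.5)


class TestWbgtFromHeatIndex:
    def test_degenerate_linear_params_reduce_to_unit_conversion(self):
        # a=0, b=5/9, c=-160/9 turns the quadratic into degF -> degC
        params = WbgtTransformParams(
            quad_a=0.0, quad_b=5 / 9, quad_c=-160 / 9, valid_hi_range=(70, 115)
        )
        for hi_c in [21.5, 30.0, 40.0]:
            assert wbgt_from_heat_index(hi_c, params) == pytest.approx(hi_c)

    def test_default_strictly_increasing_over_valid_range(self, default_params):
        lo, hi = default_params.valid_hi_range
        hi_f = np.linspace(lo, hi, 200)
        wbgt = default_params.wbgt_c(hi_f)
        assert np.all(np.diff(wbgt) > 0)
        # derivative 2a x + b positive across the range
        deriv = 2 * default_params.quad_a * hi_f + default_params.quad_b
        assert np.all(deriv > 0)

    def test_threshold_crossing_root(self, default_params):
        """Closed-form root where WBGT crosses 28 degC, checked by bisection."""
        root = default_params.hi_f_at_wbgt(28.0)
        lo, hi = default_params.valid_hi_range
        a, b = lo, hi
        for _ in range(80):  # bisection oracle on the increasing branch
            mid = 0.5 * (a + b)
            if default_params.wbgt_c(mid) < 28.0:
                a = mid
            else:
                b = mid
        assert root == pytest.approx(0.5 * (a + b), abs=1e-8)
        assert default_params.wbgt_c(root) == pytest.approx(28.0, abs=1e-9)

    def test_non_monotone_params_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WbgtTransformParams(quad_a=-0.01, quad_b=0.5, quad_c=0.0,
                                valid_hi_range=(70, 115))

    def test_outside_range_warns_not_fails(self, default_params):
        with pytest.warns(RuntimeWarning, match="trusted range"):
            wbgt_from_heat_index(5.0, default_params)

    def test_infinite_input_rejected(self, default_params):
        with pytest.raises(ValueError, match="non-finite"):
            wbgt_from_heat_index(np.inf, default_params)


class TestDailySeries:
    def test_empty_input(self, default_params):
        out = daily_wbgt_series([], [], [], default_params)
        assert len(out) == 0

    def test_single_day_equals_manual_composition(self, default_params):
        t, vpd = 33.0, 18.0
        out = daily_wbgt_series(["2019-07-01"], [t], [vpd], default_params)
        rh = relative_humidity_from_vpd(t, vpd)
        hi = heat_index(t, rh)
        assert out["hi_max"].iloc[0] == pytest.approx(hi)
        assert out["wbgt_max"].iloc[0] == pytest.approx(
            wbgt_from_heat_index(hi, default_params)
        )

    def test_year_vectorized_equals_scalar_loop(self, default_params, flat_year, rng):
        t = 20 + 15 * rng.random(len(flat_year))
        vpd = 30 * rng.random(len(flat_year))
        out = daily_wbgt_series(flat_year, t, vpd, default_params)
        for i in rng.choice(len(flat_year), size=40, replace=False):
            rh = relative_humidity_from_vpd(float(t[i]), float(vpd[i]))
            hi = heat_index(float(t[i]), float(rh))
            assert out["wbgt_max"].iloc[i] == pytest.approx(
                wbgt_from_heat_index(hi, default_params), rel=1e-12
            )

    def test_missing_days_propagate_never_drop(self, default_params, flat_year):
        t = np.full(len(flat_year), 30.0)
        t[10] = np.nan
        vpd = np.full(len(flat_year), 10.0)
        out = daily_wbgt_series(flat_year, t, vpd, default_params)
        assert len(out) == len(flat_year)
        assert np.isnan(out["wbgt_max"].iloc[10])
        assert np.isfinite(out["wbgt_max"].drop(index=10)).all()

    def test_duplicate_dates_rejected(self, default_params):
        with pytest.raises(ValueError, match="duplicate"):
            daily_wbgt_series(
                ["2019-07-01", "2019-07-01"], [30, 30], [5, 5], default_params
            )


@given(
    t=st.floats(28.0, 45.0),
    vpd1=st.floats(0.0, 40.0),
    extra=st.floats(0.1, 20.0),
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_wbgt_non_increasing_in_vpd(t, vpd1, extra):
    """More vapour-pressure deficit = drier air = no higher humid-heat burden.

    Holds for t >= 28 degC, where every humidity falls on the Rothfusz
    branch; the published procedure's simple->regression branch switch is
    discontinuous and breaks strict monotonicity in a narrow band just
    below that.
    """
    from hypothesis import assume

    params = WbgtTransformParams()
    def chain(vpd):
        rh = relative_humidity_from_vpd(t, vpd)
        return heat_index(t, rh)
    import warnings
    hi_lo_vpd, hi_hi_vpd = chain(vpd1), chain(vpd1 + extra)
    # quadratic is only monotone (and only trusted) within valid_hi_range
    assume(c_to_f(hi_lo_vpd) <= params.valid_hi_range[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        assert wbgt_from_heat_index(hi_hi_vpd, params) <= (
            wbgt_from_heat_index(hi_lo_vpd, params) + 1e-9
        )
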
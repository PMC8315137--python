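"""Carbon-balance core: interception, assimilation, demand, FBC, TAPE."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import savgol_filter

from orchard_fbc import balance
from orchard_fbc.balance import (
    DEMAND_REGRESSION_2018,
    DEMAND_REGRESSION_2019,
    DemandRegression,
    build_demand_series,
    eval_demand_regression,
    fit_demand_regression,
    gdd_canopy_date,
    lai,
    light_interception,
    p_daily,
    peak_window,
    pt_correction,
    savgol_truncated,
    tape,
    tape_per_fruit,
)
from orchard_fbc.config import OrchardParams


class TestPtCorrection:
    @pytest.mark.parametrize(
        "t,expected",
        [(0.0, 0.535), (25.7, 0.9818), (21.0, 1.0135), (50.0, 0.0)],
    )
    def test_cubic_evaluation_with_fraction_clamp(self, t, expected):
        assert float(pt_correction(t)) == pytest.approx(expected, abs=1e-3)


class TestInterception:
    def test_lai_arithmetic(self):
        assert float(lai(5.5, 3.2)) == pytest.approx(1.71875)
        assert float(lai(0.0)) == 0.0
        assert float(lai(3.2, 3.2)) == 1.0

    def test_li_saturates_at_li_max(self):
        assert float(light_interception(0.0)) == 0.0
        assert float(light_interception(1e6)) == pytest.approx(0.7)

    @pytest.mark.parametrize("la,expected", [(5.8, 0.508), (5.3, 0.486)])
    def test_printed_mean_leaf_areas_round_to_half(self, la, expected):
        li = float(light_interception(lai(la)))
        assert li == pytest.approx(expected, abs=5e-4)
        assert round(li, 1) == 0.5


class TestPDaily:
    def test_zero_radiation_or_darkness_gives_zero(self):
        assert float(p_daily(0.0, 50400, 20, 0.054, 19.8, 0.5)) == 0.0
        assert float(p_daily(17.5, 0.0, 20, 0.054, 19.8, 0.5)) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            p_daily(-1.0, 50400, 20, 0.054, 19.8, 0.5)

    def test_printed_mean_conditions_give_mid_season_tree_gain(self):
        # DL 14 h, S 17.5 MJ, T 25.7 degC, LA 5.5 m**2: around 19 g C per
        # tree and day, below the seasonal maxima of ~24-25 g d**-1
        li = float(light_interception(lai(5.5)))
        p = float(p_daily(17.5, 14 * 3600.0, 25.7, 0.054, 19.8, li))
        p_tree = p * 3.2
        assert 18.0 <= p_tree <= 21.0
        assert p_tree < 24.0

    def test_low_light_limit_is_linear_in_s(self):
        li, params = 0.5, OrchardParams()
        a = balance.alpha_energy_basis(0.054, params.ppfr_to_s)
        s = 1e-6
        slope = float(p_daily(s, 50400, 20, 0.054, 19.8, li)) / s
        assert slope == pytest.approx(a * li * 0.27, rel=1e-4)


class TestGdd:
    def test_constant_temperature_crossing_day(self):
        w = pd.DataFrame({"dafb": np.arange(1, 201), "t_mean": 14.0})
        assert gdd_canopy_date(w) == 120.0

    def test_never_reached_raises(self):
        w = pd.DataFrame({"dafb": np.arange(1, 201), "t_mean": 3.0})
        with pytest.raises(ValueError):
            gdd_canopy_date(w)

    def test_default_weather_reaches_full_canopy_in_season(self, default_run_tables):
        d = gdd_canopy_date(default_run_tables["weather"])
        assert 0 < d < 116


class TestSmoothing:
    def test_interior_matches_scipy_savgol(self, rng):
        y = rng.normal(size=60)
        ours = savgol_truncated(y, 9, 1)
        scipy_ref = savgol_filter(y, 9, 1)
        np.testing.assert_allclose(ours[4:-4], scipy_ref[4:-4], atol=1e-10)

    def test_constant_series_preserved(self):
        y = np.full(30, 3.7)
        np.testing.assert_allclose(savgol_truncated(y), y)

    def test_linearity(self, rng):
        y = rng.normal(size=40)
        np.testing.assert_allclose(
            savgol_truncated(2.0 * y), 2.0 * savgol_truncated(y), atol=1e-10
        )


class TestDemandSeries:
    def test_demand_doubles_with_requirement(self):
        agr = np.full(50, 0.1)
        rc = np.full(50, 0.01)
        p = np.full(50, 5.0)
        raw1, _ = balance.la_demand_series(agr, rc, p, 1.7)
        raw2, _ = balance.la_demand_series(2 * agr, 2 * rc, p, 1.7)
        np.testing.assert_allclose(raw2, 2 * raw1)

    def test_constant_inputs_smooth_equals_raw(self):
        raw, smooth = balance.la_demand_series(
            np.full(40, 0.1), np.full(40, 0.01), np.full(40, 5.0), 1.7
        )
        np.testing.assert_allclose(raw, smooth, rtol=1e-12)

    def test_windowed_demand_near_regression_scale(self, default_run_tables):
        # the default season at LA 5.5 and D 65 should be on the few-hundred
        # cm**2 scale of the published surfaces
        grid = default_run_tables["grid"]
        val = float(
            grid[(grid["d"] == 65.0) & (grid["la"] == 5.5)]["la_demand"].iloc[0]
        )
        assert 300.0 < val < 700.0


class TestPeakWindow:
    def _table(self, req, dafb=None):
        if dafb is None:
            dafb = np.arange(len(req), dtype=float)
        return pd.DataFrame(
            {"dafb": dafb, "target_d": 65.0, "agr_c": req, "rc_daily": 0.0}
        )

    def test_peak_at_100_gives_85_115(self):
        dafb = np.arange(0.0, 121.0)
        req = np.exp(-0.5 * ((dafb - 100) / 12.0) ** 2)
        assert peak_window(self._table(req, dafb)) == (85.0, 115.0)

    def test_early_peak_clipped_at_season_start(self):
        dafb = np.arange(0.0, 121.0)
        req = np.exp(-0.5 * ((dafb - 10) / 6.0) ** 2)
        assert peak_window(self._table(req, dafb)) == (0.0, 25.0)

    def test_monotone_requirement_ends_at_harvest(self):
        dafb = np.arange(0.0, 121.0)
        assert peak_window(self._table(dafb * 0.01, dafb)) == (105.0, 120.0)


class TestFBC:
    def test_unit_demand_gives_single_fruit(self):
        table = pd.DataFrame(
            {
                "dafb": np.arange(100.0),
                "target_d": 65.0,
                "agr_c": 1.0,
                "rc_daily": 0.0,
                "la_demand_smooth": 5.5e4,
            }
        )
        ds = balance.DemandSeries(table, (40.0, 70.0), 5.5, 1.72, 0.5)
        assert ds.fbc(65.0) == 1

    @pytest.mark.parametrize(
        "reg,d,expected_demand,expected_fbc",
        [
            (DEMAND_REGRESSION_2018, 65.0, 422.25, 130),
            (DEMAND_REGRESSION_2018, 70.0, 557.52, 98),
            (DEMAND_REGRESSION_2019, 80.0, 773.43, 71),
        ],
    )
    def test_published_surface_chain(self, reg, d, expected_demand, expected_fbc):
        assert eval_demand_regression(reg, d, 5.5) == pytest.approx(
            expected_demand, abs=0.01
        )
        assert reg.fbc(d, 5.5) == expected_fbc

    def test_fbc_monotone_in_la_and_diameter(self, default_run_tables):
        fbc = default_run_tables["fbc"].sort_values("la_m2")
        assert fbc["fbc_65"].is_monotonic_increasing
        arr = fbc[["fbc_65", "fbc_70", "fbc_75", "fbc_80"]].to_numpy()
        assert (np.diff(arr, axis=1) <= 0).all()


class TestDemandRegression:
    def test_exact_recovery_from_surface_data(self):
        d, la = np.meshgrid([65.0, 70, 75, 80], [2.7, 3.6, 5.5, 7.7, 9.5])
        y = DEMAND_REGRESSION_2018.demand(d.ravel(), la.ravel())
        fit = fit_demand_regression(
            pd.DataFrame({"d": d.ravel(), "la": la.ravel(), "la_demand": y})
        )
        assert fit.intercept == pytest.approx(-714.6813, abs=1e-8)
        assert fit.d_coef == pytest.approx(14.4682, abs=1e-8)
        assert fit.la_coef == pytest.approx(-113.006, abs=1e-8)
        assert fit.dla_coef == pytest.approx(2.2882, abs=1e-8)

    def test_degenerate_la_zero_still_defined(self):
        reg = DEMAND_REGRESSION_2018
        assert reg.demand(65.0, 0.0) == pytest.approx(-714.6813 + 14.4682 * 65.0)


class TestTape:
    def test_arithmetic(self):
        w = pd.DataFrame({"dafb": np.arange(50.0), "s": 10.0})
        t = tape(0.5, w, (0.0, 49.0))  # sum S = 500 MJ m**-2
        assert t == pytest.approx(0.5 * 500 * 0.5 * 3.2)

    def test_zero_radiation(self):
        w = pd.DataFrame({"dafb": np.arange(10.0), "s": 0.0})
        assert tape(0.5, w, (0.0, 9.0)) == 0.0

    def test_per_fruit_requires_fruit(self):
        with pytest.raises(ValueError):
            tape_per_fruit(400.0, 0)
        assert tape_per_fruit(400.0, 80) == pytest.approx(5.0)


class TestFbcTableConsistency:
    def test_matches_per_tree_demand_series(self, default_run, default_run_tables):
        import json

        from orchard_fbc.respiration import RespirationModel

        gx = default_run_tables["gas_exchange"]
        resp = RespirationModel.from_json(str(default_run / "respiration_model.json"))
        fbc = default_run_tables["fbc"]
        weather = default_run_tables["weather"]
        curves = default_run_tables["curves"]
        for _, row in fbc.iloc[[3, 500, 997]].iterrows():
            ds = build_demand_series(
                weather, curves, resp, float(row["la_m2"]),
                gx["max_alpha"], gx["max_j_nonstomatal"],
            )
            assert ds.fbc(65.0) == int(row["fbc_65"])
            assert ds.fbc(80.0) == int(row["fbc_80"])
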
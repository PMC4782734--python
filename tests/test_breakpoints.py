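"""Temperature-index breakpoint detection: formulas, oracles, trend models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamtemp import breakpoints as bp


class TestTempIndex:
    @pytest.mark.parametrize(
        "water, air, expected",
        [(10.0, 10.0, 0.0), (10.0, 5.0, 0.5), (8.0, 12.0, -0.5)],
    )
    def test_formula(self, water, air, expected):
        assert bp.temp_index(water, air) == pytest.approx(expected)

    @pytest.mark.parametrize("water, air", [(0.0, 5.0), (-1.0, 5.0), (np.nan, 5.0), (5.0, np.nan)])
    def test_invalid_cases(self, water, air):
        assert np.isnan(bp.temp_index(water, air))

    @given(
        w=st.floats(0.1, 40), a=st.floats(-30, 40), c=st.floats(0.01, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_free(self, w, a, c):
        assert bp.temp_index(c * w, c * a) == pytest.approx(bp.temp_index(w, a), rel=1e-9)


class TestMovingAverage:
    def test_constant_series(self):
        out = bp.moving_average(np.full(40, 3.7))
        assert np.allclose(out[5:-5], 3.7)

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(15, 80)
            x = rng.normal(size=n)
            x[rng.random(n) < 0.3] = np.nan
            got = bp.moving_average(x, window=10, min_valid=5)
            for i in range(n):
                lo, hi = max(0, i - 5), min(n, i + 5)
                vals = x[lo:hi][np.isfinite(x[lo:hi])]
                if len(vals) >= 5:
                    assert got[i] == pytest.approx(vals.mean(), abs=1e-12)
                else:
                    assert np.isnan(got[i])

    def test_all_invalid_window_gives_invalid(self):
        x = np.full(30, np.nan)
        assert np.isnan(bp.moving_average(x)).all()

    def test_window_below_one_rejected(self):
        with pytest.raises(bp.BreakpointError):
            bp.moving_average(np.ones(10), window=0)


class TestFlatPeriodCI:
    def test_constant_index_degenerate_interval(self):
        doy = np.arange(100, 300)
        ci = bp.flat_period_ci(np.full(200, 0.25), doy)
        assert ci == (0.25, 0.25)

    def test_matches_sort_based_quantile_oracle(self):
        vals = np.arange(1.0, 1001.0)
        doy = np.arange(1, 1001)
        lo, hi = bp.flat_period_ci(vals, doy, mid_days=(1, 1000), level=0.999)

        def type7(sorted_v, q):
            h = (len(sorted_v) - 1) * q
            f = int(np.floor(h))
            return sorted_v[f] + (h - f) * (sorted_v[min(f + 1, len(sorted_v) - 1)] - sorted_v[f])

        s = np.sort(vals)
        assert lo == pytest.approx(type7(s, 0.0005))
        assert hi == pytest.approx(type7(s, 0.9995))

    def test_too_few_days_undetectable(self):
        doy = np.array([130, 131])
        assert bp.flat_period_ci(np.array([0.1, 0.2]), doy) is None

    def test_normal_reference_method(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.1, 0.2, 150)
        doy = np.arange(125, 275)
        lo, hi = bp.flat_period_ci(vals, doy, method="normal")
        assert (hi - lo) == pytest.approx(2 * 3.2905 * vals.std(ddof=1), rel=1e-3)


def bruteforce_breakpoints(smoothed, ci, run_len=10, mid_day=150):
    """Naive O(days * run_len) scan used as the independent oracle."""
    lo, hi = ci
    n = len(smoothed)
    inside = [np.isfinite(v) and lo <= v <= hi for v in smoothed]
    spring = None
    for d in range(1, mid_day + 1):
        if d + run_len - 1 <= n and all(inside[k - 1] for k in range(d, d + run_len)):
            spring = d
            break
    fall = None
    for d in range(n, mid_day - 1, -1):
        if d - run_len + 1 >= 1 and all(inside[k - 1] for k in range(d - run_len + 1, d + 1)):
            fall = d
            break
    return spring, fall


class TestDetectBreakpoints:
    def test_always_synchronized_limit(self):
        n = 360
        sm = np.zeros(n)
        assert bp.detect_breakpoints(sm, np.arange(1, n + 1), (-0.1, 0.1)) == (1, n)

    def test_constructed_window_100_280(self):
        n = 365
        sm = np.full(n, 5.0)  # far outside
        sm[99:280] = 0.0  # doy 100..280 inside
        spring, fall = bp.detect_breakpoints(sm, np.arange(1, n + 1), (-0.1, 0.1))
        assert (spring, fall) == (100, 280)
        assert bruteforce_breakpoints(sm, (-0.1, 0.1)) == (100, 280)

    def test_single_bad_day_delays_run(self):
        n = 365
        sm = np.full(n, 5.0)
        sm[99:280] = 0.0
        sm[103] = 5.0  # doy 104 breaks the run
        spring, _ = bp.detect_breakpoints(sm, np.arange(1, n + 1), (-0.1, 0.1))
        assert spring == 105

    def test_no_qualifying_run_flagged(self):
        n = 365
        sm = np.full(n, 5.0)
        assert bp.detect_breakpoints(sm, np.arange(1, n + 1), (-0.1, 0.1)) == (None, None)

    def test_agrees_with_bruteforce_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(160, 370))
            sm = rng.normal(0, 1, n)
            sm[rng.random(n) < 0.15] = np.nan
            ci = tuple(np.sort(rng.normal(0, 1, 2)))
            got = bp.detect_breakpoints(sm, np.arange(1, n + 1), ci)
            assert got == bruteforce_breakpoints(sm, ci)

    def test_invariant_to_winter_days_beyond_run_boundaries(self):
        n = 365
        sm = np.full(n, 5.0)
        sm[99:280] = 0.0
        base = bp.detect_breakpoints(sm, np.arange(1, n + 1), (-0.1, 0.1))
        sm2 = sm.copy()
        sm2[:80] = np.nan  # winter values irrelevant
        sm2[300:] = -999.0
        assert bp.detect_breakpoints(sm2, np.arange(1, n + 1), (-0.1, 0.1)) == base


class TestSummaries:
    def _frame(self, doy, water):
        dates = pd.to_datetime("2001-01-01") + pd.to_timedelta(doy - 1, unit="D")
        return pd.DataFrame(
            {"site": "WB", "date": dates, "year": 2001, "doy": doy, "waterT": water,
             "airT": 10.0, "flow": 1.0}
        )

    def test_full_data_window_count(self):
        doy = np.arange(1, 366)
        df = self._frame(doy, np.full(365, 12.0))
        win = pd.DataFrame(
            [{"site": "WB", "year": 2001, "spring_day": 100, "fall_day": 280}]
        )
        out = bp.summarize_windows(win, df)
        assert out.loc[0, "n_days"] == 181
        assert out.loc[0, "pct_missing"] == 0.0

    def test_masked_days_counted(self):
        doy = np.arange(1, 366)
        water = np.full(365, 12.0)
        water[119:209] = np.nan  # 90 masked days inside 100..280
        df = self._frame(doy, water)
        win = pd.DataFrame(
            [{"site": "WB", "year": 2001, "spring_day": 100, "fall_day": 280}]
        )
        out = bp.summarize_windows(win, df)
        assert out.loc[0, "n_days"] == 91
        assert out.loc[0, "pct_missing"] == pytest.approx(round(100 * 90 / 181, 1))

    def test_no_data_site_year_zero(self):
        doy = np.arange(1, 366)
        df = self._frame(doy, np.full(365, np.nan))
        win = pd.DataFrame(
            [{"site": "WB", "year": 2001, "spring_day": 100, "fall_day": 280}]
        )
        assert bp.summarize_windows(win, df).loc[0, "n_days"] == 0


class TestBreakpointTrend:
    def _windows(self, slope, n_years=15, base=280.0, noise=None, seed=0, sites=("WB", "OL")):
        rng = np.random.default_rng(seed)
        rows = []
        years = np.arange(2000, 2000 + n_years)
        for s in sites:
            for y in years:
                day = base + slope * (y - years.mean())
                if noise:
                    day += rng.normal(0, noise)
                rows.append({"site": s, "year": y, "spring_day": 100, "fall_day": day})
        return pd.DataFrame(rows)

    def test_exact_linear_slope_recovered_to_machine_precision(self):
        win = self._windows(slope=1.33)
        res = bp.breakpoint_trend(win, "fall")
        assert res["slope"] == pytest.approx(1.33, abs=1e-10)
        assert res["decadal"] == pytest.approx(13.3, abs=1e-9)

    def test_tie_breaks_to_simplest_model(self):
        # one site only: site terms cannot be fit, year-only must be chosen
        win = self._windows(slope=0.5, sites=("WB",), noise=3, seed=2)
        res = bp.breakpoint_trend(win, "fall")
        assert res["chosen"] == "year"

    def test_parsimony_rule_within_two_aic(self):
        win = self._windows(slope=1.0, noise=5, seed=3)
        res = bp.breakpoint_trend(win, "fall")
        aics = res["aic"]
        best = min(aics.values())
        # chosen model is the first (simplest) within 2 of the minimum
        order = ["year", "year+site", "year*site"]
        expected = next(n for n in order if aics[n] <= best + 2)
        assert res["chosen"] == expected

    def test_too_few_site_years_rejected(self):
        win = self._windows(slope=1.0).head(2)
        with pytest.raises(bp.BreakpointError):
            bp.breakpoint_trend(win, "fall")


def test_compute_windows_on_synthetic(tiny_sim):
    df, truth = tiny_sim
    win = bp.compute_windows(df)
    found = win.dropna(subset=["spring_day", "fall_day"])
    assert len(found) == len(win)  # every site-year detectable without missingness
    for _, w in found.iterrows():
        sp, fa = truth.windows[(w["site"], int(w["year"]))]
        assert w["spring_day"] <= 150 <= w["fall_day"]
        assert w["ci_lo"] < w["ci_hi"]
        assert w["n_sync_days"] <= w["fall_day"] - w["spring_day"] + 1
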
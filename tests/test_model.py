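"""Design matrices, densities (vs independent oracles), posterior products."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamtemp.model import (
    ModelError,
    Standardization,
    build_design,
    conditional_mean,
    cubic_peak,
    linear_predictor,
    log_likelihood,
    log_posterior,
    max_temp_trend,
    rhat,
)
from tests.conftest import random_params


def small_frame(doy, water, site="WB", year=2001, air=None, flow=None):
    dates = pd.to_datetime(f"{year}-01-01") + pd.to_timedelta(np.asarray(doy) - 1, unit="D")
    n = len(doy)
    return pd.DataFrame(
        {
            "site": site,
            "date": dates,
            "year": year,
            "doy": doy,
            "airT": air if air is not None else np.linspace(5, 15, n),
            "waterT": water,
            "flow": flow if flow is not None else np.ones(n),
        }
    )


def windows_frame(site="WB", year=2001, spring=100, fall=102):
    return pd.DataFrame(
        [{"site": site, "year": year, "spring_day": spring, "fall_day": fall}]
    )


class TestBuildDesign:
    def test_contiguity_flags_full_data(self):
        df = small_frame(np.arange(95, 110), np.full(15, 12.0))
        data = build_design(df, windows_frame(), std="none")
        assert data.n_rows == 3
        assert list(data.prev_available) == [False, True, True]

    def test_gap_breaks_contiguity(self):
        water = np.full(15, 12.0)
        water[6] = np.nan  # doy 101
        df = small_frame(np.arange(95, 110), water)
        data = build_design(df, windows_frame(), std="none")
        assert data.n_rows == 2
        assert list(data.prev_available) == [False, False]

    def test_standardization_none_passes_raw_covariates(self):
        df = small_frame(np.arange(95, 110), np.full(15, 12.0))
        data = build_design(df, windows_frame(), std="none")
        sub = df.iloc[5:8]
        assert np.allclose(data.X_fixed[:, 1], sub["airT"])
        assert np.allclose(data.X_fixed[:, 4], sub["flow"])
        assert np.allclose(data.X_year[:, 1], sub["doy"])

    def test_air_lags_from_year_round_series(self):
        df = small_frame(np.arange(95, 110), np.full(15, 12.0), air=np.arange(15.0))
        data = build_design(df, windows_frame(), std="none")
        # window starts at doy 100 = position 5; lags reach back to 3, 4
        assert np.allclose(data.X_fixed[0, 1:4], [5.0, 4.0, 3.0])

    def test_unknown_site_rejected(self):
        df = small_frame(np.arange(95, 110), np.full(15, 12.0))
        with pytest.raises(ModelError):
            build_design(df, windows_frame(site="??"), std="none", sites=("WB",))

    def test_missing_covariate_inside_window_rejected(self):
        air = np.linspace(5, 15, 15)
        air[6] = np.nan
        df = small_frame(np.arange(95, 110), np.full(15, 12.0), air=air)
        with pytest.raises(ModelError):
            build_design(df, windows_frame(), std="none")


class TestLinearPredictor:
    def _tiny(self):
        df = small_frame(np.arange(95, 110), np.full(15, 12.0), air=np.full(15, 2.0))
        return build_design(df, windows_frame(), std="none")

    def _params(self, rng=None, **kw):
        p = random_params(np.random.default_rng(0), 1, (2001,))
        p.beta[:] = 0.0
        p.B[:] = 0.0
        p.alpha = 15.0
        for k, v in kw.items():
            setattr(p, k, v)
        return p

    def test_intercept_only(self):
        data = self._tiny()
        p = self._params()
        assert np.allclose(linear_predictor(p, data), 15.0)

    def test_single_air_term(self):
        data = self._tiny()
        p = self._params()
        p.beta[0] = 1.52  # airT = 2 on the raw scale -> 15 + 3.04
        assert np.allclose(linear_predictor(p, data), 18.04)

    def test_matches_term_by_term_oracle(self, tiny_design):
        rng = np.random.default_rng(3)
        data = tiny_design
        for _ in range(5):
            p = random_params(rng, len(data.sites), data.years)
            got = linear_predictor(p, data)
            want = np.empty(data.n_rows)
            for i in range(data.n_rows):
                acc = p.alpha
                for j in range(11):
                    acc += p.beta[j] * data.X_fixed[i, j + 1]
                b = p.B[data.year_idx[i]]
                for k in range(4):
                    acc += b[k] * data.X_year[i, k]
                want[i] = acc
            assert np.max(np.abs(got - want)) < 1e-12

    def test_missing_year_rejected(self):
        data = self._tiny()
        p = self._params()
        p.b_years = (1999,)
        with pytest.raises(ModelError):
            linear_predictor(p, data)


class TestConditionalMean:
    def test_delta_zero_ignores_history(self, tiny_design):
        p = random_params(np.random.default_rng(1), len(tiny_design.sites), tiny_design.years)
        p.delta[:] = 0.0
        assert np.allclose(
            conditional_mean(p, tiny_design), linear_predictor(p, tiny_design)
        )

    def test_unit_carryover_at_boundary(self):
        df = small_frame(np.arange(95, 110), np.linspace(10, 14, 15))
        data = build_design(df, windows_frame(), std="none")
        p = random_params(np.random.default_rng(2), 1, (2001,))
        p.delta[:] = 1.0  # boundary: mu = omega + previous residual exactly
        omega = linear_predictor(p, data)
        mu = conditional_mean(p, data)
        assert mu[0] == omega[0]
        assert mu[1] == pytest.approx(omega[1] + (data.y[0] - omega[0]))

    def test_break_in_series_uses_no_ar_path(self):
        water = np.full(15, 12.0)
        water[6] = np.nan
        df = small_frame(np.arange(95, 110), water)
        data = build_design(df, windows_frame(), std="none")
        p = random_params(np.random.default_rng(2), 1, (2001,))
        p.delta[:] = 0.9
        assert np.allclose(conditional_mean(p, data), linear_predictor(p, data))


def oracle_log_posterior(p, data):
    """Independent density-by-density summation (loops + explicit formulas)."""
    obs = np.where(data.obs_mask)[0]
    omega = np.empty(data.n_rows)
    for i in range(data.n_rows):
        omega[i] = (
            p.alpha
            + float(np.dot(p.beta, data.X_fixed[i, 1:]))
            + float(np.dot(p.B[data.year_idx[i]], data.X_year[i]))
        )
    lp = 0.0
    for i in obs:
        j = data.prev_idx[i]
        mu = omega[i]
        if j >= 0:
            mu += p.delta[data.site_idx[i]] * (data.y[j] - omega[j])
        z = (data.y[i] - mu) / p.sd
        lp += -0.5 * z * z - np.log(p.sd) - 0.5 * np.log(2 * np.pi)
    # delta hierarchy: truncated normal with normalizer
    for d in p.delta:
        z = (d - p.mu_delta) / p.sd_delta
        norm = stats.norm.cdf((1 - p.mu_delta) / p.sd_delta) - stats.norm.cdf(
            (-1 - p.mu_delta) / p.sd_delta
        )
        lp += -0.5 * z * z - np.log(p.sd_delta) - 0.5 * np.log(2 * np.pi) - np.log(norm)
    # year effects: MVN via explicit quadratic form
    sign, logdet = np.linalg.slogdet(p.Sigma)
    P = np.linalg.inv(p.Sigma)
    for row in np.atleast_2d(p.B):
        d = row - p.M
        lp += -0.5 * (d @ P @ d) - 0.5 * logdet - 2 * np.log(2 * np.pi)
    # priors
    for v in [p.alpha, *p.beta, *p.M[1:]]:
        lp += -0.5 * (v / 10.0) ** 2 - np.log(10.0) - 0.5 * np.log(2 * np.pi)
    lp += stats.invwishart.logpdf(p.Sigma, 5, np.eye(4))
    return lp


class TestLogPosterior:
    def test_single_row_at_mean_likelihood(self):
        df = small_frame([98, 99, 100], [np.nan, np.nan, 15.0])
        data = build_design(df, windows_frame(spring=100, fall=100), std="none")
        p = random_params(np.random.default_rng(0), 1, (2001,))
        p.alpha, p.sd = 15.0, 1.0
        p.beta[:] = 0.0
        p.B[:] = 0.0
        assert log_likelihood(p, data) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_delta_outside_support_is_neg_inf(self, tiny_design):
        p = random_params(np.random.default_rng(4), len(tiny_design.sites), tiny_design.years)
        p.delta[0] = 1.0
        assert log_posterior(p, tiny_design) == -np.inf

    @pytest.mark.parametrize("field, value", [("sd", 11.0), ("sd_delta", 2.5), ("mu_delta", 1.2)])
    def test_prior_support_enforced(self, tiny_design, field, value):
        p = random_params(np.random.default_rng(4), len(tiny_design.sites), tiny_design.years)
        setattr(p, field, value)
        assert log_posterior(p, tiny_design) == -np.inf

    def test_matches_bruteforce_oracle(self, tiny_design):
        rng = np.random.default_rng(5)
        rows = np.arange(20)
        import dataclasses

        small = dataclasses.replace(
            tiny_design,
            df=tiny_design.df.iloc[rows],
            y=tiny_design.y[rows],
            X_fixed=tiny_design.X_fixed[rows],
            X_year=tiny_design.X_year[rows],
            site_idx=tiny_design.site_idx[rows],
            year_idx=tiny_design.year_idx[rows],
            prev_idx=np.where(tiny_design.prev_idx[rows] < 20, tiny_design.prev_idx[rows], -1),
            obs_mask=tiny_design.obs_mask[rows],
        )
        for _ in range(10):
            p = random_params(rng, len(small.sites), small.years)
            assert log_posterior(p, small) == pytest.approx(
                oracle_log_posterior(p, small), abs=1e-8
            )


class TestRhat:
    def test_identical_chains_finite_sample_value(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=200)
        chains = np.stack([c, c])
        n = 200
        assert rhat(chains) == pytest.approx(np.sqrt((n - 1) / n))

    def test_same_distribution_converged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 10_000))
        assert rhat(chains) < 1.01

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])
        assert rhat(chains) > 1.1

    def test_zero_within_variance_undefined(self):
        chains = np.zeros((2, 100))
        assert np.isnan(rhat(chains))

    def test_matches_hand_coded_formula(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 300)) + rng.normal(size=(4, 1))
        m, n = chains.shape
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B = n * np.var(chains.mean(axis=1), ddof=1)
        expect = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(chains) == pytest.approx(expect, rel=1e-12)


class TestCubicPeak:
    def test_downward_parabola(self):
        mx, am, edge = cubic_peak([0.0, 0.0, -1.0, 0.0])
        assert mx == pytest.approx(0.0)
        assert am == pytest.approx(0.0)
        assert not edge

    def test_analytic_vertex_identity(self):
        c = np.array([1.0, 0.8, -2.0, 0.3])
        mx, am, _ = cubic_peak(c)
        # argmax solves 3 c3 u^2 + 2 c2 u + c1 = 0
        assert 3 * c[3] * am**2 + 2 * c[2] * am + c[1] == pytest.approx(0.0, abs=1e-10)

    def test_monotone_cubic_takes_edge(self):
        mx, am, edge = cubic_peak([0.0, 1.0, 0.0, 0.0])
        assert (am, mx) == (1.0, 1.0)
        assert edge

    def test_matches_grid_search(self):
        rng = np.random.default_rng(6)
        grid = np.arange(-1, 1 + 1e-9, 1e-3)
        U = np.column_stack([np.ones_like(grid), grid, grid**2, grid**3])
        for _ in range(100):
            c = rng.normal(0, 2, 4)
            mx, am, _ = cubic_peak(c)
            vals = U @ c
            k = np.argmax(vals)
            assert abs(am - grid[k]) <= 1e-3 + 1e-9
            assert mx >= vals[k] - 1e-12


class TestMaxTempTrend:
    def test_exact_linear_decadal_rate(self):
        years = np.arange(1999, 2014)
        vals = 17.0 + 0.063 * (years - years[0])
        res = max_temp_trend(vals, years)
        assert res["decadal"] == pytest.approx(0.63, abs=1e-12)

    def test_constant_series(self):
        years = np.arange(2000, 2010)
        res = max_temp_trend(np.full(10, 17.0), years)
        assert res["slope"] == 0.0
        assert res["F"] == 0.0

    def test_too_few_years_rejected(self):
        with pytest.raises(ModelError):
            max_temp_trend([1.0, 2.0], [2000, 2001])

    def test_monte_carlo_slope_unbiased(self):
        rng = np.random.default_rng(8)
        years = np.arange(1999, 2014)
        slopes = []
        for _ in range(500):
            vals = 17.0 + 0.063 * (years - years.mean()) + rng.normal(0, 0.3, len(years))
            slopes.append(max_temp_trend(vals, years)["slope"])
        assert abs(np.mean(slopes) - 0.063) < 0.01


def test_predictions_invariant_to_standardization(tiny_sim, tiny_cfg):
    """Two standardization specs span the same model space: the linear
    predictor is reproducible across specs after an exact reparameterization."""
    df, truth = tiny_sim
    win = truth.windows_frame()
    d1 = build_design(df, win, std=truth.std, sites=tiny_cfg.sites, observed_only=False)
    alt = Standardization(
        mode="standard", air_center=10.0, air_scale=3.0, flow_center=0.1,
        flow_scale=0.7, log_flow=True, day_min=50.0, day_max=330.0,
    )
    d2 = build_design(df, win, std=alt, sites=tiny_cfg.sites, observed_only=False)

    def full_matrix(d):
        n, Y = d.n_rows, len(d.years)
        Z = np.zeros((n, 4 * Y))
        for j in range(Y):
            rows = d.year_idx == j
            Z[rows, 4 * j : 4 * j + 4] = d.X_year[rows]
        return np.hstack([d.X_fixed, Z])

    X1, X2 = full_matrix(d1), full_matrix(d2)
    rng = np.random.default_rng(9)
    theta1 = rng.normal(0, 1, X1.shape[1])
    omega1 = X1 @ theta1
    theta2, *_ = np.linalg.lstsq(X2, omega1, rcond=None)
    assert np.max(np.abs(X2 @ theta2 - omega1)) < 1e-8
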
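"""Model assessment: goodness of fit, leave-p-out CV, and the quantity /
timing / location missing-data experiment designs.

Every experiment follows the same template: mask part of the observed water
record, refit the model on the remainder (scaled-down MCMC by default),
predict the masked rows, and report train/test RMSE plus the difference from
the all-data base case.  Predictions of masked rows use the no-AR mean
whenever the previous day's water is itself masked, so no information leaks
through the autoregressive term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelData, Posterior, build_design, predict
from .sampler import MCMCConfig, sample_posterior

P_GRID = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


class AssessmentError(ValueError):
    pass


@dataclass
class ExperimentResult:
    scheme: str
    params: dict
    replicate: int
    rmse_train: float
    rmse_test: float | None
    rmse_diff_from_base: float | None
    n_test_rows: int

    def to_row(self) -> dict:
        row = {
            "scheme": self.scheme,
            "replicate": self.replicate,
            "rmse_train": self.rmse_train,
            "rmse_test": self.rmse_test,
            "rmse_diff": self.rmse_diff_from_base,
            "n_test_rows": self.n_test_rows,
        }
        row.update(self.params)
        return row


def rmse(observed, predicted) -> float:
    """Root mean square error of residuals, in degC."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise AssessmentError("observed and predicted must have equal length")
    if obs.size == 0:
        raise AssessmentError("rmse of an empty series is undefined")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def observed_vs_predicted(observed, predicted) -> dict:
    """OLS regression of observed on predicted: slope, intercept, s.e., R^2."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if np.std(pred) == 0 or len(obs) < 3:
        raise AssessmentError("degenerate predictions: zero variance")
    res = stats.linregress(pred, obs)
    return {
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "intercept": float(res.intercept),
        "intercept_se": float(res.intercept_stderr),
        "r2": float(res.rvalue**2),
        "n": int(len(obs)),
    }


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------


@dataclass
class BaseFit:
    """The all-data fit every scenario is compared against."""

    data: ModelData
    posterior: Posterior
    rmse: float
    windows: pd.DataFrame
    df: pd.DataFrame
    mcmc: MCMCConfig
    seed: int


def fit_base(
    df: pd.DataFrame,
    windows: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> BaseFit:
    """Fit the model on all observed in-window rows and score its RMSE."""
    mcmc = mcmc or MCMCConfig.reduced()
    data = build_design(df, windows, observed_only=False)
    post = sample_posterior(data, mcmc, seed=seed)
    obs_rows = np.where(data.obs_mask)[0]
    pred = predict(post, data, rows=obs_rows, mode="one_step", seed=seed)
    base_rmse = rmse(data.y[obs_rows], pred["mean"].to_numpy())
    return BaseFit(data, post, base_rmse, windows, df, mcmc, seed)


def _run_scenario(
    base: BaseFit,
    test_keys: set,
    scheme: str,
    params: dict,
    replicate: int,
    seed: int,
    score_sites: set | None = None,
) -> ExperimentResult:
    """Mask the water rows named by (site, date) keys, refit, score.

    Train and test rows partition the base observed rows exactly; the
    assertion guards against leakage.
    """
    df = base.df
    keys = list(zip(df["site"], pd.to_datetime(df["date"])))
    test_mask = np.array([k in test_keys for k in keys])
    test_mask &= df["waterT"].notna().to_numpy()

    masked = df.copy()
    masked.loc[test_mask, "waterT"] = np.nan
    data = build_design(masked, base.windows, observed_only=False)

    # no-leakage partition check on the full in-window grid
    grid_keys = list(zip(data.df["site"], pd.to_datetime(data.df["date"])))
    truth_map = {
        k: w
        for k, w in zip(keys, df["waterT"])
        if np.isfinite(w)
    }
    is_test = np.array([(k in test_keys) and (k in truth_map) for k in grid_keys])
    assert not np.any(is_test & data.obs_mask), "test rows leaked into training"

    post = sample_posterior(data, base.mcmc, seed=seed)
    obs_rows = np.where(data.obs_mask)[0]
    pred_train = predict(post, data, rows=obs_rows, mode="one_step", seed=seed)
    r_train = rmse(data.y[obs_rows], pred_train["mean"].to_numpy())

    if score_sites is not None:
        in_score = data.df["site"].isin(score_sites).to_numpy()
        is_test &= in_score
    test_rows = np.where(is_test)[0]
    if len(test_rows) == 0:
        return ExperimentResult(scheme, params, replicate, r_train, None, None, 0)
    pred_test = predict(post, data, rows=test_rows, mode="one_step", seed=seed)
    y_true = np.array([truth_map[grid_keys[i]] for i in test_rows])
    r_test = rmse(y_true, pred_test["mean"].to_numpy())
    return ExperimentResult(
        scheme, params, replicate, r_train, r_test, r_test - base.rmse, len(test_rows)
    )


def _observed_inwindow_keys(base: BaseFit) -> list:
    d = base.data.df
    keys = list(zip(d["site"], pd.to_datetime(d["date"])))
    return [k for k, o in zip(keys, base.data.obs_mask) if o]


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------


def leave_p_out(
    base: BaseFit,
    p_grid=P_GRID,
    reps: int = 10,
    seed: int = 0,
) -> list[ExperimentResult]:
    """Randomly mask a proportion p of observed water rows, for each p and
    replicate.  p = 0 reports the base case (no test rows)."""
    keys = _observed_inwindow_keys(base)
    results = []
    for p in p_grid:
        for rep in range(reps):
            rng = np.random.default_rng(
                [seed % (2**31), int(round(p * 1000)), rep]
            )
            if p == 0:
                results.append(
                    ExperimentResult(
                        "leave_p_out", {"p": 0.0}, rep, base.rmse, None, None, 0
                    )
                )
                continue
            n_drop = int(round(p * len(keys)))
            chosen = rng.choice(len(keys), size=n_drop, replace=False)
            test = {keys[i] for i in chosen}
            results.append(
                _run_scenario(
                    base, test, "leave_p_out", {"p": float(p)}, rep,
                    seed=_sub_seed(seed, 1, int(p * 1000), rep),
                )
            )
            if p > 0:
                assert results[-1].n_test_rows == n_drop
    return results


def quantity_scenarios(
    base: BaseFit, d_values=range(1, 10), trim_per_d: int = 15, seed: int = 0
) -> list[ExperimentResult]:
    """Trim 15*d observed days from both ends of every site-year series.

    A site-year whose series is shorter than the trim is fully left out for
    that scenario.  Returns one result per d; proportion-retained is recorded
    so a slope of RMSE-difference vs retained fraction can be fit.
    """
    d_df = base.data.df
    obs = base.data.obs_mask
    per_sy: dict = {}
    for (s, y), g in d_df.loc[obs].groupby(["site", "year"]):
        g = g.sort_values("date")
        per_sy[(s, y)] = list(zip(g["site"], pd.to_datetime(g["date"])))
    n_total = sum(len(v) for v in per_sy.values())
    results = []
    for d in d_values:
        trim = trim_per_d * int(d)
        test = set()
        for sy, days in per_sy.items():
            if len(days) <= 2 * trim:
                test.update(days)
            else:
                test.update(days[:trim])
                test.update(days[-trim:])
        res = _run_scenario(
            base, test, "quantity", {"d": int(d)}, 0, seed=_sub_seed(seed, 2, int(d))
        )
        res.params["prop_retained"] = 1.0 - len(test) / n_total
        results.append(res)
    return results


def timing_starts(
    n_windows: int = 13, first_start: int = 70, last_start: int = 310,
    window_len: int = 30, mode: str = "overlapping",
) -> list[int]:
    """Start days of the timing scenarios.

    "overlapping" (default): ``n_windows`` evenly spaced starts from
    first_start to last_start.  "strict": as many non-overlapping windows of
    ``window_len`` days as fit in the range.
    """
    if mode == "overlapping":
        return [int(round(s)) for s in np.linspace(first_start, last_start, n_windows)]
    if mode == "strict":
        return list(range(first_start, last_start + 1, window_len))
    raise AssessmentError(f"unknown timing mode {mode!r}")


def timing_scenarios(
    base: BaseFit,
    target_site: str,
    companions: bool = True,
    n_windows: int = 13,
    window_len: int = 30,
    first_start: int = 70,
    last_start: int = 310,
    mode: str = "overlapping",
    seed: int = 0,
) -> list[ExperimentResult]:
    """Retain only one 30-day window of the target site's water data.

    With ``companions`` the other sites keep their full records; without it
    they are restricted to the same window (their masked rows are excluded
    from scoring — the test set is the target site's masked rows only).
    """
    starts = timing_starts(n_windows, first_start, last_start, window_len, mode)
    d_df = base.data.df
    obs = base.data.obs_mask
    keys = list(zip(d_df["site"], pd.to_datetime(d_df["date"])))
    doy = d_df["doy"].to_numpy()
    site = d_df["site"].to_numpy()
    results = []
    for k, start in enumerate(starts):
        in_win = (doy >= start) & (doy <= start + window_len - 1)
        if companions:
            drop = obs & (site == target_site) & ~in_win
        else:
            drop = obs & ~in_win
        n_train = int((obs & ~drop).sum())
        if n_train < 20:  # window outside sync coverage: flag, don't fit
            results.append(
                ExperimentResult(
                    "timing",
                    {"start": int(start), "companions": bool(companions),
                     "sparse": True, "n_target_retained": 0},
                    k, np.nan, None, None, 0,
                )
            )
            continue
        test = {keys[i] for i in np.where(drop)[0]}
        res = _run_scenario(
            base, test, "timing",
            {"start": int(start), "companions": bool(companions)},
            k, seed=_sub_seed(seed, 3, k, int(companions)),
            score_sites={target_site},
        )
        n_kept = int((obs & (site == target_site) & in_win).sum())
        res.params["n_target_retained"] = n_kept
        results.append(res)
    return results


def holdout_scenarios(
    base: BaseFit, target: str = "one-site", target_site: str | None = None, seed: int = 0
) -> list[ExperimentResult]:
    """Year-at-a-time holdout: mask the target's whole water record per year.

    target "one-site" masks only ``target_site`` (default: the first site,
    the mainstem analog); "all-sites" masks every site for the year, so the
    held-out year's effects come purely from partial pooling.
    """
    if target not in ("one-site", "all-sites"):
        raise AssessmentError(f"unknown holdout target {target!r}")
    d_df = base.data.df
    obs = base.data.obs_mask
    if target_site is None:
        target_site = base.data.sites[0]
    years = sorted(set(d_df.loc[obs, "year"].astype(int)))
    if len(years) < 2:
        raise AssessmentError("year holdout needs >=2 years of data")
    keys = list(zip(d_df["site"], pd.to_datetime(d_df["date"])))
    site = d_df["site"].to_numpy()
    yr = d_df["year"].to_numpy()
    results = []
    for k, year in enumerate(years):
        sel = obs & (yr == year)
        if target == "one-site":
            sel &= site == target_site
        if not sel.any():
            continue
        test = {keys[i] for i in np.where(sel)[0]}
        results.append(
            _run_scenario(
                base, test, f"holdout_{target}", {"year": int(year)}, k,
                seed=_sub_seed(seed, 4, k, int(target == "all-sites")),
            )
        )
    return results


def _sub_seed(seed: int, *parts: int) -> int:
    x = seed % (2**31)
    for p in parts:
        x = (x * 1_000_003 + p + 1) % (2**31)
    return x


def results_frame(results: list[ExperimentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def table3_summary(base: BaseFit, results: list[ExperimentResult]) -> dict:
    """Aggregate the battery into the all-data / random-30% / holdout shape."""
    frame = results_frame(results)
    out = {"all_data_rmse": base.rmse}
    lp = frame[(frame["scheme"] == "leave_p_out")]
    if len(lp):
        lp30 = lp[np.isclose(lp.get("p", np.nan), 0.3)]
        if len(lp30):
            out["p30_rmse_train"] = float(lp30["rmse_train"].mean())
            out["p30_rmse_test"] = float(lp30["rmse_test"].mean())
            out["p30_rmse_diff"] = float(lp30["rmse_diff"].mean())
    for scheme, label in (
        ("holdout_one-site", "one_site_holdout"),
        ("holdout_all-sites", "all_sites_holdout"),
    ):
        sub = frame[frame["scheme"] == scheme]
        if len(sub):
            out[f"{label}_rmse_test"] = float(sub["rmse_test"].mean())
            out[f"{label}_rmse_diff"] = float(sub["rmse_diff"].mean())
    return out
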
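"""Air-water synchronization breakpoints via the temperature-index runs analysis.

For each site-year, the dimensionless index (waterT - airT) / waterT (defined
only where waterT > 0) is near 0 while water and air track each other and
diverges in winter.  The flat period's typical values are bounded by an
empirical 99.9% percentile interval of the raw index over the middle of the
year; a centered 10-day moving average of the index is then scanned for the
first run of 10 consecutive days inside that interval from the start of the
year (spring breakpoint) and from the end of the year backwards (fall
breakpoint).  Trends in breakpoints across years are compared with nested
linear models selected by AIC parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

MID_DAYS = (125, 274)  # 150-day flat-period reference range
CI_LEVEL = 0.999
MA_WINDOW = 10
RUN_LENGTH = 10
MID_DAY = 150  # spring scan ends / fall scan starts here
MIN_CI_DAYS = 30
MIN_MA_VALID = 5


class BreakpointError(ValueError):
    pass


@dataclass
class SyncWindow:
    """One site-year's detected synchronization window."""

    site: str
    year: int
    spring_day: int | None
    fall_day: int | None
    ci_lo: float | None
    ci_hi: float | None
    n_sync_days_with_data: int = 0
    pct_missing_in_window: float = np.nan

    @property
    def found(self) -> bool:
        return self.spring_day is not None and self.fall_day is not None


def temp_index(waterT, airT):
    """(waterT - airT) / waterT where waterT > 0 and both observed; NaN otherwise."""
    w = np.asarray(waterT, dtype=float)
    a = np.asarray(airT, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((w > 0) & np.isfinite(w) & np.isfinite(a), (w - a) / w, np.nan)
    if np.isscalar(waterT) and np.isscalar(airT):
        return float(out)
    return out


def moving_average(
    x: np.ndarray, window: int = MA_WINDOW, min_valid: int = MIN_MA_VALID,
    center: str = "left",
) -> np.ndarray:
    """Centered moving average over a daily series with invalid (NaN) days.

    Each output day is the mean of the valid values in its window; the output
    is NaN when fewer than ``min_valid`` inputs are valid.  An even window is
    left-heavy by default (window//2 days before through window//2 - 1 after);
    ``center="right"`` selects the alternative.  Windows truncate at the
    series edges.
    """
    if window < 1:
        raise BreakpointError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = len(x)
    valid = np.isfinite(x)
    filled = np.where(valid, x, 0.0)
    if center == "left":
        before, after = window // 2, window - window // 2 - 1
    elif center == "right":
        before, after = window - window // 2 - 1, window // 2
    else:
        raise BreakpointError(f"unknown centering {center!r}")
    # cumulative sums for O(n) truncated-window means
    cs = np.concatenate([[0.0], np.cumsum(filled)])
    cn = np.concatenate([[0], np.cumsum(valid.astype(int))])
    i = np.arange(n)
    lo = np.maximum(0, i - before)
    hi = np.minimum(n, i + after + 1)
    counts = cn[hi] - cn[lo]
    sums = cs[hi] - cs[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(counts >= min_valid, sums / np.maximum(counts, 1), np.nan)
    return out


def flat_period_ci(
    raw_index: np.ndarray,
    doy: np.ndarray,
    mid_days: tuple[int, int] = MID_DAYS,
    level: float = CI_LEVEL,
    min_days: int = MIN_CI_DAYS,
    method: str = "percentile",
) -> tuple[float, float] | None:
    """Interval bounding typical flat-period index values over mid-year.

    "percentile" (default): empirical two-sided percentile interval of the
    raw daily values.  "normal": normal reference range mean +/- z*sd, which
    has far less sampling noise at extreme levels (a 0.05% empirical quantile
    from ~150 days is essentially that year's minimum).  Returns None
    (window undetectable) when fewer than ``min_days`` valid index days fall
    inside ``mid_days``.
    """
    raw_index = np.asarray(raw_index, float)
    doy = np.asarray(doy)
    sel = (doy >= mid_days[0]) & (doy <= mid_days[1]) & np.isfinite(raw_index)
    vals = raw_index[sel]
    if len(vals) < min_days:
        return None
    if method == "percentile":
        tail = (1.0 - level) / 2.0
        lo, hi = np.quantile(vals, [tail, 1.0 - tail])
    elif method == "normal":
        from scipy.stats import norm

        z = norm.ppf(1.0 - (1.0 - level) / 2.0)
        m, s = vals.mean(), vals.std(ddof=1)
        lo, hi = m - z * s, m + z * s
    else:
        raise BreakpointError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


def detect_breakpoints(
    smoothed: np.ndarray,
    doy: np.ndarray,
    ci: tuple[float, float],
    run_len: int = RUN_LENGTH,
    mid_day: int = MID_DAY,
) -> tuple[int | None, int | None]:
    """Runs analysis on the smoothed index.

    Spring breakpoint: scanning doy 1 -> mid_day, the first day d whose
    ``run_len`` consecutive days d..d+run_len-1 are all valid and inside
    [ci_lo, ci_hi].  Fall: scanning from the year's end toward mid_day, the
    first day d whose backward run d-run_len+1..d qualifies.  Days with
    invalid smoothed values break a run.  Returns (spring, fall) with None
    for a side with no qualifying run.
    """
    smoothed = np.asarray(smoothed, float)
    doy = np.asarray(doy, int)
    lo, hi = ci
    by_day = {}
    for d, v in zip(doy, smoothed):
        by_day[int(d)] = v
    max_day = int(doy.max()) if len(doy) else 0

    def inside(d):
        v = by_day.get(d, np.nan)
        return np.isfinite(v) and lo <= v <= hi

    spring = None
    for d in range(1, mid_day + 1):
        if all(inside(d + k) for k in range(run_len)):
            spring = d
            break
    fall = None
    for d in range(max_day, mid_day - 1, -1):
        if all(inside(d - k) for k in range(run_len)):
            fall = d
            break
    return spring, fall


def compute_windows(
    df: pd.DataFrame,
    mid_days: tuple[int, int] = MID_DAYS,
    level: float = CI_LEVEL,
    ma_window: int = MA_WINDOW,
    run_len: int = RUN_LENGTH,
    mid_day: int = MID_DAY,
    min_ci_days: int = MIN_CI_DAYS,
    min_ma_valid: int = MIN_MA_VALID,
) -> pd.DataFrame:
    """Detect a SyncWindow for every site-year of a canonical table."""
    out = []
    for (site, year), g in df.groupby(["site", "year"], sort=True):
        g = g.sort_values("doy")
        doy = g["doy"].to_numpy(int)
        raw = temp_index(g["waterT"].to_numpy(), g["airT"].to_numpy())
        ci = flat_period_ci(raw, doy, mid_days=mid_days, level=level, min_days=min_ci_days)
        if ci is None:
            out.append(SyncWindow(site, int(year), None, None, None, None))
            continue
        # moving average over the full consecutive-doy grid
        full = np.full(int(doy.max()), np.nan)
        full[doy - 1] = raw
        sm = moving_average(full, window=ma_window, min_valid=min_ma_valid)
        spring, fall = detect_breakpoints(
            sm, np.arange(1, len(full) + 1), ci, run_len=run_len, mid_day=mid_day
        )
        w = SyncWindow(site, int(year), spring, fall, ci[0], ci[1])
        if w.found:
            inside = (doy >= spring) & (doy <= fall)
            with_data = inside & g["waterT"].notna().to_numpy()
            w.n_sync_days_with_data = int(with_data.sum())
            total = fall - spring + 1
            w.pct_missing_in_window = round(100.0 * (1 - with_data.sum() / total), 1)
        out.append(w)
    return pd.DataFrame(
        [
            {
                "site": w.site,
                "year": w.year,
                "spring_day": w.spring_day,
                "fall_day": w.fall_day,
                "ci_lo": w.ci_lo,
                "ci_hi": w.ci_hi,
                "n_sync_days": w.n_sync_days_with_data,
                "pct_missing": w.pct_missing_in_window,
            }
            for w in out
        ]
    )


def summarize_windows(windows: pd.DataFrame, df: pd.DataFrame) -> pd.DataFrame:
    """Per site-year synchronized-day counts (the shape of the field study's
    deployment table): days with water data inside the window and the percent
    of in-window days missing; zeros for site-years with no detected window
    or no data."""
    rows = []
    obs = df.dropna(subset=["waterT"])
    counts = obs.groupby(["site", "year"])["doy"].apply(set).to_dict()
    for _, w in windows.iterrows():
        site, year = w["site"], int(w["year"])
        days = counts.get((site, year), set())
        if pd.isna(w["spring_day"]) or pd.isna(w["fall_day"]):
            rows.append({"site": site, "year": year, "n_days": 0, "pct_missing": np.nan})
            continue
        sp, fa = int(w["spring_day"]), int(w["fall_day"])
        inside = {d for d in days if sp <= d <= fa}
        total = fa - sp + 1
        rows.append(
            {
                "site": site,
                "year": year,
                "n_days": len(inside),
                "pct_missing": round(100.0 * (1 - len(inside) / total), 1),
            }
        )
    return pd.DataFrame(rows)


def breakpoint_trend(
    windows: pd.DataFrame, season: str, delta_aic: float = 2.0
) -> dict:
    """Trend in breakpoint day across years, with AIC-based model selection.

    Fits three nested OLS models of breakpoint day: ~ year, ~ year + site,
    ~ year * site, and selects the simplest model whose AIC is within
    ``delta_aic`` of the minimum.  Returns per-model AICs, the chosen model,
    its year slope and the decadal rate (slope x 10).
    """
    col = {"spring": "spring_day", "fall": "fall_day"}[season]
    d = windows.dropna(subset=[col]).copy()
    d["day"] = d[col].astype(float)
    d["year_c"] = d["year"].astype(float)
    if len(d) < 3:
        raise BreakpointError(f"need >=3 site-years with a {season} breakpoint")
    formulas = {
        "year": "day ~ year_c",
        "year+site": "day ~ year_c + C(site)",
        "year*site": "day ~ year_c * C(site)",
    }
    order = list(formulas)
    fits, aics = {}, {}
    for name, f in formulas.items():
        if name != "year" and d["site"].nunique() < 2:
            continue
        res = smf.ols(f, data=d).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise BreakpointError(f"rank-deficient design in model {name!r} (site term)")
        fits[name] = res
        aics[name] = float(res.aic)
    best = min(aics.values())
    chosen = next(n for n in order if n in aics and aics[n] <= best + delta_aic)
    res = fits[chosen]
    slope = float(res.params["year_c"])
    return {
        "season": season,
        "aic": aics,
        "chosen": chosen,
        "slope": slope,
        "decadal": slope * 10.0,
        "p_value": float(res.pvalues["year_c"]),
        "f_stat": float(res.fvalue),
        "r2": float(res.rsquared),
        "n": int(len(d)),
    }


def trend_report(windows: pd.DataFrame, delta_aic: float = 2.0) -> dict:
    """Spring and fall trends plus the decadal widening of the window."""
    spring = breakpoint_trend(windows, "spring", delta_aic)
    fall = breakpoint_trend(windows, "fall", delta_aic)
    return {
        "spring": spring,
        "fall": fall,
        "widening_per_decade": (fall["slope"] - spring["slope"]) * 10.0,
    }
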
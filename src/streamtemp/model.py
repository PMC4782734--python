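"""Hierarchical daily water-temperature model for the air-water synchronized season.

Within each site-year synchronization window, observed daily mean water
temperature t[s,d,y] is normal around a mean that combines a linear predictor
omega with an AR(1) adjustment on the previous day's residual:

    t[s,d,y] ~ N(mu[s,d,y], sd)
    mu[s,d,y] = omega[s,d,y] + delta_s * (t[s,d-1,y] - omega[s,d-1,y])

falling back to mu = omega at the start of a series or after a gap.  The
linear predictor has fixed effects (air temperature at lags 0-2, flow, an
air x flow interaction, site offsets and site x air interactions) plus a
year-level random cubic in day of year:

    omega = alpha + b1*T + b2*T(-1) + b3*T(-2) + b4*F + b5*T*F
            + site offsets + site x T + B_y . (1, D, D^2, D^3)

with B_y ~ MVN(M, Sigma) pooled across years.  Priors: alpha, b1..b11 and the
free components of M are N(0, 100); delta_s ~ N(mu_delta, sd_delta) truncated
to (-1, 1); mu_delta ~ U(-1, 1); sd_delta ~ U(0, 2); sd ~ U(0, 10);
Sigma ~ inv-Wishart(I_4, df=5).  M[0] (the hyper-mean of the yearly intercept)
is fixed at 0 for identifiability with alpha.

Covariates are standardized by default: air temperature and log flow are
centered and scaled over training rows, and day of year is mapped linearly to
[-1, 1] over the union of synchronization windows before building the cubic.
The constants are stored for back-transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

N_FIXED = 12  # intercept + beta1..beta11
N_YEAR = 4  # 1, D, D^2, D^3

#: prior scales / supports
BETA_PRIOR_SD = 10.0  # N(0, 100)
SD_UPPER = 10.0
SD_DELTA_UPPER = 2.0
WISHART_DF = 5  # l + 1 with l = 4
FIXED_NAMES = (
    "alpha",
    "airT",
    "airT_lag1",
    "airT_lag2",
    "flow",
    "airT_x_flow",
    "site2",
    "site3",
    "site4",
    "site2_x_airT",
    "site3_x_airT",
    "site4_x_airT",
)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardization:
    """Covariate transforms applied before the design matrix is built.

    mode "standard": air centered/scaled, flow log-transformed (optional)
    then centered/scaled, day of year mapped linearly to [-1, 1] over
    [day_min, day_max].  mode "none": raw covariates pass through.
    """

    mode: str = "standard"
    air_center: float = 0.0
    air_scale: float = 1.0
    flow_center: float = 0.0
    flow_scale: float = 1.0
    log_flow: bool = True
    day_min: float = 1.0
    day_max: float = 366.0

    @classmethod
    def none(cls) -> "Standardization":
        return cls(mode="none", log_flow=False)

    @classmethod
    def from_rows(
        cls, air: np.ndarray, flow: np.ndarray, doy: np.ndarray, log_flow: bool = True
    ) -> "Standardization":
        f = np.log(flow) if log_flow else np.asarray(flow, float)
        return cls(
            mode="standard",
            air_center=float(np.nanmean(air)),
            air_scale=float(np.nanstd(air)) or 1.0,
            flow_center=float(np.nanmean(f)),
            flow_scale=float(np.nanstd(f)) or 1.0,
            log_flow=log_flow,
            day_min=float(np.min(doy)),
            day_max=float(np.max(doy)),
        )

    def air(self, x):
        if self.mode == "none":
            return np.asarray(x, float)
        return (np.asarray(x, float) - self.air_center) / self.air_scale

    def flow(self, x):
        x = np.asarray(x, float)
        if self.mode == "none":
            return x
        f = np.log(x) if self.log_flow else x
        return (f - self.flow_center) / self.flow_scale

    def day(self, doy):
        if self.mode == "none":
            return np.asarray(doy, float)
        span = self.day_max - self.day_min
        if span <= 0:
            return np.zeros_like(np.asarray(doy, float))
        return 2.0 * (np.asarray(doy, float) - self.day_min) / span - 1.0

    def day_inverse(self, u):
        if self.mode == "none":
            return np.asarray(u, float)
        return (np.asarray(u, float) + 1.0) / 2.0 * (self.day_max - self.day_min) + self.day_min

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "air_center": self.air_center,
            "air_scale": self.air_scale,
            "flow_center": self.flow_center,
            "flow_scale": self.flow_scale,
            "log_flow": self.log_flow,
            "day_min": self.day_min,
            "day_max": self.day_max,
        }


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """One full parameter point of the hierarchical model.

    ``beta`` holds beta1..beta11 in the order of :data:`FIXED_NAMES` (without
    the intercept).  ``B`` is (n_years, 4) aligned with ``b_years``.
    """

    alpha: float
    beta: np.ndarray  # (11,)
    B: np.ndarray  # (n_years, 4): alpha_y, b12, b13, b14
    b_years: tuple  # years aligned with rows of B
    M: np.ndarray  # (4,), M[0] fixed at 0
    Sigma: np.ndarray  # (4, 4)
    delta: np.ndarray  # (n_sites,)
    mu_delta: float
    sd_delta: float
    sd: float

    def theta_fixed(self) -> np.ndarray:
        return np.concatenate([[self.alpha], np.asarray(self.beta, float)])

    def in_support(self) -> bool:
        ok = (
            np.all(np.abs(self.delta) < 1)
            and -1 < self.mu_delta < 1
            and 0 < self.sd_delta < SD_DELTA_UPPER
            and 0 < self.sd < SD_UPPER
            and abs(self.M[0]) < 1e-12
        )
        if not ok:
            return False
        S = np.asarray(self.Sigma, float)
        if not np.allclose(S, S.T):
            return False
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return False
        return True

    def year_row(self, year: int) -> np.ndarray:
        try:
            j = self.b_years.index(year)
        except ValueError as err:
            raise ModelError(f"year {year} absent from B_y") from err
        return self.B[j]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class ModelData:
    """Model-ready arrays for in-window rows of the canonical table."""

    df: pd.DataFrame  # site, date, year, doy, airT, waterT, flow per retained row
    y: np.ndarray  # waterT (NaN where unobserved, only if observed_only=False)
    X_fixed: np.ndarray  # (n, 12)
    X_year: np.ndarray  # (n, 4)
    site_idx: np.ndarray
    year_idx: np.ndarray
    sites: tuple
    years: tuple
    prev_idx: np.ndarray  # row index of previous observed in-window day, -1 if none
    obs_mask: np.ndarray  # water observed
    std: Standardization

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def prev_available(self) -> np.ndarray:
        return self.prev_idx >= 0


def build_covariates(
    df: pd.DataFrame, std: Standardization, sites: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Build (X_fixed, X_year) for rows of ``df``.

    Requires columns airT, airT_lag1, airT_lag2, flow, doy, site.  The first
    site in ``sites`` is the reference level (mainstem).
    """
    t0 = std.air(df["airT"].to_numpy())
    t1 = std.air(df["airT_lag1"].to_numpy())
    t2 = std.air(df["airT_lag2"].to_numpy())
    f = std.flow(df["flow"].to_numpy())
    n = len(df)
    site_idx = np.array([sites.index(s) for s in df["site"]])
    Xf = np.zeros((n, N_FIXED))
    Xf[:, 0] = 1.0
    Xf[:, 1] = t0
    Xf[:, 2] = t1
    Xf[:, 3] = t2
    Xf[:, 4] = f
    Xf[:, 5] = t0 * f
    for k in range(1, len(sites)):
        ind = (site_idx == k).astype(float)
        Xf[:, 5 + k] = ind
        Xf[:, 8 + k] = ind * t0
    u = std.day(df["doy"].to_numpy())
    Xy = np.column_stack([np.ones(n), u, u**2, u**3])
    return Xf, Xy


def build_design(
    df: pd.DataFrame,
    windows: pd.DataFrame,
    std: Standardization | str = "standard",
    sites: tuple | None = None,
    observed_only: bool = True,
    log_flow: bool = True,
) -> ModelData:
    """Assemble model-ready arrays from a canonical table and detected windows.

    ``windows`` needs columns site, year, spring_day, fall_day.  Rows are
    restricted to in-window days; with ``observed_only`` (the default) only
    days with observed water remain, otherwise the full in-window grid is kept
    (with ``obs_mask`` marking observed water) so that held-out rows can be
    predicted.  ``std`` may be a :class:`Standardization`, "standard" (compute
    constants from the retained observed rows) or "none".

    The previous-day flag is true iff the immediately preceding calendar day
    is also an in-window *observed* row for the same site-year.
    """
    if sites is None:
        sites = tuple(pd.unique(df["site"]))
    unknown = set(windows["site"]) - set(sites)
    if unknown:
        raise ModelError(f"unknown site(s) in windows: {sorted(unknown)}")

    df = df.sort_values(["site", "date"]).reset_index(drop=True)
    # air lags from the full (year-round) air series, per site
    g = df.groupby("site", sort=False)
    df = df.assign(
        airT_lag1=g["airT"].shift(1).to_numpy(),
        airT_lag2=g["airT"].shift(2).to_numpy(),
    )
    # a one-day gap in the table itself would corrupt the shift
    day_gap = g["date"].diff().dt.days.to_numpy()
    df.loc[(day_gap != 1) & ~np.isnan(day_gap), ["airT_lag1", "airT_lag2"]] = np.nan
    gap2 = g["date"].diff(2).dt.days.to_numpy()
    df.loc[(gap2 != 2) & ~np.isnan(gap2), "airT_lag2"] = np.nan

    win = {}
    for _, row in windows.iterrows():
        sp, fa = row["spring_day"], row["fall_day"]
        if pd.isna(sp) or pd.isna(fa):
            continue
        win[(row["site"], int(row["year"]))] = (int(sp), int(fa))

    keys = list(zip(df["site"], df["year"]))
    doy = df["doy"].to_numpy()
    in_win = np.array(
        [k in win and win[k][0] <= d <= win[k][1] for k, d in zip(keys, doy)]
    )
    if np.isnan(df.loc[in_win, ["airT", "airT_lag1", "airT_lag2", "flow"]].to_numpy()).any():
        raise ModelError("missing air/flow covariates inside a synchronization window")

    sub = df.loc[in_win].copy()
    if observed_only:
        sub = sub.loc[~sub["waterT"].isna()].copy()
    sub = sub.reset_index(drop=True)
    obs = ~sub["waterT"].isna().to_numpy()

    if isinstance(std, str):
        if std == "none":
            std = Standardization.none()
        elif std == "standard":
            train = sub.loc[obs]
            if not len(train):
                raise ModelError("no observed in-window rows to standardize over")
            std = Standardization.from_rows(
                train["airT"].to_numpy(), train["flow"].to_numpy(), sub["doy"].to_numpy(),
                log_flow=log_flow,
            )
        else:
            raise ModelError(f"unknown standardization mode {std!r}")

    Xf, Xy = build_covariates(sub, std, sites)
    years = tuple(sorted(set(int(y) for y in sub["year"])))
    year_idx = np.array([years.index(int(y)) for y in sub["year"]])
    site_idx = np.array([sites.index(s) for s in sub["site"]])

    # previous observed in-window calendar day, same site-year
    loc = {}
    dates = sub["date"].to_numpy()
    for i, (s, d, o) in enumerate(zip(sub["site"], dates, obs)):
        if o:
            loc[(s, d)] = i
    one_day = np.timedelta64(1, "D")
    prev_idx = np.full(len(sub), -1, dtype=int)
    for i, (s, d) in enumerate(zip(sub["site"], dates)):
        j = loc.get((s, d - one_day), -1)
        if j >= 0 and sub["year"].iat[j] == sub["year"].iat[i]:
            prev_idx[i] = j

    return ModelData(
        df=sub,
        y=sub["waterT"].to_numpy(dtype=float),
        X_fixed=Xf,
        X_year=Xy,
        site_idx=site_idx,
        year_idx=year_idx,
        sites=tuple(sites),
        years=years,
        prev_idx=prev_idx,
        obs_mask=obs,
        std=std,
    )


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def linear_predictor(params: ModelParams, data: ModelData, rows=None) -> np.ndarray:
    """omega for each row: fixed effects plus the row's year-level cubic."""
    Xf, Xy, yi = data.X_fixed, data.X_year, data.year_idx
    if rows is not None:
        Xf, Xy, yi = Xf[rows], Xy[rows], yi[rows]
    Bmap = np.array([params.year_row(y) for y in data.years])
    return Xf @ params.theta_fixed() + np.einsum("ij,ij->i", Xy, Bmap[yi])


def conditional_mean(params: ModelParams, data: ModelData) -> np.ndarray:
    """mu: omega adjusted by delta_s times yesterday's residual where available."""
    omega = linear_predictor(params, data)
    mu = omega.copy()
    # prev_idx only ever points at observed rows, so prev_available suffices
    rows = np.where(data.prev_available)[0]
    prev = data.prev_idx[rows]
    mu[rows] += params.delta[data.site_idx[rows]] * (data.y[prev] - omega[prev])
    return mu


def _truncnorm_logpdf(x, loc, scale, lo=-1.0, hi=1.0):
    z = stats.norm.logpdf(x, loc, scale)
    norm = stats.norm.cdf(hi, loc, scale) - stats.norm.cdf(lo, loc, scale)
    return z - np.log(norm)


def log_likelihood(params: ModelParams, data: ModelData) -> float:
    """Normal log-likelihood of observed water temperatures at the
    AR(1)-adjusted conditional mean."""
    obs = data.obs_mask
    mu = conditional_mean(params, data)
    return float(np.sum(stats.norm.logpdf(data.y[obs], mu[obs], params.sd)))


def log_posterior(params: ModelParams, data: ModelData) -> float:
    """Unnormalized log posterior density (likelihood + hierarchy + priors).

    Returns -inf for parameters outside the prior support; numeric failures
    raise instead of returning -inf.
    """
    if not params.in_support():
        return -np.inf
    lp = log_likelihood(params, data)
    lp += float(
        np.sum(_truncnorm_logpdf(params.delta, params.mu_delta, params.sd_delta))
    )
    lp += float(
        stats.multivariate_normal.logpdf(params.B, params.M, params.Sigma).sum()
    )
    # priors
    theta = params.theta_fixed()
    lp += float(np.sum(stats.norm.logpdf(theta, 0.0, BETA_PRIOR_SD)))
    lp += float(np.sum(stats.norm.logpdf(params.M[1:], 0.0, BETA_PRIOR_SD)))
    lp += float(
        stats.invwishart.logpdf(params.Sigma, WISHART_DF, np.eye(N_YEAR))
    )
    # mu_delta, sd_delta, sd: uniform on their supports (constants)
    return lp


# ---------------------------------------------------------------------------
# posterior container and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class Posterior:
    """Retained MCMC samples, one array per parameter block.

    Arrays are shaped (chains, draws, *block); ``sites``/``years``/``std``
    carry the design metadata needed for prediction.
    """

    samples: dict
    sites: tuple
    years: tuple
    std: Standardization
    n_chains: int
    burn_in: int
    iterations: int
    thin: int
    seed: int

    @property
    def n_draws(self) -> int:
        return self.samples["sd"].shape[1]

    def scalar_items(self):
        """Yield (name, (chains, draws) array) for every sampled scalar."""
        for name, arr in self.samples.items():
            if arr.ndim == 2:
                yield name, arr
            else:
                flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
                for k in range(flat.shape[2]):
                    yield f"{name}[{k}]", flat[:, :, k]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: (chains*draws, *block)."""
        arr = self.samples[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def params_at(self, k: int) -> ModelParams:
        """Materialize the k-th pooled draw as a ModelParams."""
        g = lambda n: self.stacked(n)[k]
        return ModelParams(
            alpha=float(g("alpha")),
            beta=g("beta"),
            B=g("B"),
            b_years=self.years,
            M=g("M"),
            Sigma=g("Sigma"),
            delta=g("delta"),
            mu_delta=float(g("mu_delta")),
            sd_delta=float(g("sd_delta")),
            sd=float(g("sd")),
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.scalar_items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.percentile(flat, 2.5),
                    "q50": np.percentile(flat, 50),
                    "q97.5": np.percentile(flat, 97.5),
                    "rhat": rhat(arr),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (parameter, chain, iteration, value) table."""
        recs = []
        for name, arr in self.scalar_items():
            for c in range(arr.shape[0]):
                recs.append(
                    pd.DataFrame(
                        {
                            "parameter": name,
                            "chain": c,
                            "iteration": np.arange(arr.shape[1]),
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def max_rhat(self) -> float:
        return max(rhat(arr) for _, arr in self.scalar_items())


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Uses the classic between/within
    variance ratio: sqrt(((n-1)/n * W + B/n) / W).  Returns NaN when the
    within-chain variance is zero (undefined).
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ModelError("rhat needs >=2 chains and >=10 draws")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        return np.nan
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(
    posterior: Posterior,
    data: ModelData,
    rows: np.ndarray | None = None,
    mode: str = "one_step",
    observed_water: np.ndarray | None = None,
    seed: int = 0,
    max_draws: int = 400,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Posterior predictive summaries for the requested rows of ``data``.

    mode "one_step" applies the AR(1) adjustment wherever the previous
    calendar day's water temperature is available in ``observed_water``
    (default: the training observations in ``data``); rows without it fall
    back to the no-AR mean, mirroring the model's own rule for series breaks.
    mode "free_running" always uses the no-AR mean.  Years absent from the
    posterior receive year effects drawn from the hyperdistribution
    MVN(M, Sigma) — the partial-pooling fallback.

    Returns a DataFrame with the posterior mean of mu (``mean``), its credible
    bounds and predictive-interval bounds (observation noise included).
    """
    if mode not in ("one_step", "free_running"):
        raise ModelError(f"unknown prediction mode {mode!r}")
    if rows is None:
        rows = np.arange(data.n_rows)
    rows = np.asarray(rows)
    if observed_water is None:
        observed_water = np.where(data.obs_mask, data.y, np.nan)

    rng = np.random.default_rng([seed, posterior.seed % (2**31)])
    total = posterior.n_chains * posterior.n_draws
    take = np.linspace(0, total - 1, min(max_draws, total)).astype(int)

    alpha_s = posterior.stacked("alpha")[take]
    beta_s = posterior.stacked("beta")[take]
    B_s = posterior.stacked("B")[take]
    M_s = posterior.stacked("M")[take]
    Sig_s = posterior.stacked("Sigma")[take]
    delta_s = posterior.stacked("delta")[take]
    sd_s = posterior.stacked("sd")[take]

    # map each data year to a posterior B column, or draw from the hyperprior
    nd = len(take)
    B_use = np.empty((nd, len(data.years), N_YEAR))
    for j, year in enumerate(data.years):
        if year in posterior.years:
            B_use[:, j] = B_s[:, posterior.years.index(year)]
        else:
            for k in range(nd):
                B_use[k, j] = rng.multivariate_normal(M_s[k], Sig_s[k])

    theta = np.column_stack([alpha_s, beta_s])  # (nd, 12)
    need = set(rows.tolist())
    ar_prev = {}
    if mode == "one_step":
        for i in rows:
            j = data.prev_idx[i]
            if j >= 0 and np.isfinite(observed_water[j]):
                ar_prev[i] = j
                need.add(j)
    idx = np.array(sorted(need))
    pos = {i: k for k, i in enumerate(idx)}

    omega = theta @ data.X_fixed[idx].T  # (nd, m)
    omega += np.einsum("kmj,mj->km", B_use[:, data.year_idx[idx]], data.X_year[idx])

    mu = np.empty((nd, len(rows)))
    for c, i in enumerate(rows):
        m = omega[:, pos[i]]
        j = ar_prev.get(i)
        if j is not None:
            m = m + delta_s[:, data.site_idx[i]] * (observed_water[j] - omega[:, pos[j]])
        mu[:, c] = m

    lo = (1 - interval) / 2 * 100
    pred_draws = mu + rng.standard_normal(mu.shape) * sd_s[:, None]
    return pd.DataFrame(
        {
            "row": rows,
            "mean": mu.mean(axis=0),
            "mu_lo": np.percentile(mu, lo, axis=0),
            "mu_hi": np.percentile(mu, 100 - lo, axis=0),
            "pred_lo": np.percentile(pred_draws, lo, axis=0),
            "pred_hi": np.percentile(pred_draws, 100 - lo, axis=0),
        }
    )


# ---------------------------------------------------------------------------
# yearly cubic curves and trends
# ---------------------------------------------------------------------------


def cubic_peak(coefs: np.ndarray, lo: float = -1.0, hi: float = 1.0):
    """Analytic (max value, argmax) of c0 + c1 u + c2 u^2 + c3 u^3 on [lo, hi].

    Critical points are the real roots of 3 c3 u^2 + 2 c2 u + c1; the maximum
    is taken over interior critical points and the interval edges.  Returns
    (max, argmax, at_edge).
    """
    c0, c1, c2, c3 = (float(c) for c in coefs)
    cand = [lo, hi]
    a, b, c = 3 * c3, 2 * c2, c1
    if abs(a) > 1e-300:
        disc = b * b - 4 * a * c
        if disc >= 0:
            r = np.sqrt(disc)
            for u in ((-b + r) / (2 * a), (-b - r) / (2 * a)):
                if lo < u < hi:
                    cand.append(u)
    elif abs(b) > 1e-300:
        u = -c / b
        if lo < u < hi:
            cand.append(u)
    vals = [c0 + c1 * u + c2 * u**2 + c3 * u**3 for u in cand]
    k = int(np.argmax(vals))
    return vals[k], cand[k], k < 2


def cubic_curves(
    posterior: Posterior,
    years: tuple | None = None,
    n_grid: int = 201,
    max_draws: int = 400,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year seasonal cubic (alpha + year effect) and its peak.

    Other covariates are held at their standardized zero (training means).
    Returns (curves, peaks): ``curves`` has posterior-mean temperature on a
    day grid per year; ``peaks`` has posterior mean and 95% bounds of the
    yearly maximum and its day of year.
    """
    if years is None:
        years = posterior.years
    std = posterior.std
    total = posterior.n_chains * posterior.n_draws
    take = np.linspace(0, total - 1, min(max_draws, total)).astype(int)
    alpha_s = posterior.stacked("alpha")[take]
    B_s = posterior.stacked("B")[take]

    u = np.linspace(-1, 1, n_grid)
    day = std.day_inverse(u)
    U = np.column_stack([np.ones_like(u), u, u**2, u**3])

    curve_rows, peak_rows = [], []
    for year in years:
        j = posterior.years.index(year)
        coefs = B_s[:, j].copy()  # (nd, 4)
        coefs[:, 0] += alpha_s
        vals = coefs @ U.T
        curve_rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "doy": day,
                    "mean": vals.mean(axis=0),
                    "lo": np.percentile(vals, 2.5, axis=0),
                    "hi": np.percentile(vals, 97.5, axis=0),
                }
            )
        )
        peaks = np.array([cubic_peak(c) for c in coefs])
        mx, am = peaks[:, 0], std.day_inverse(peaks[:, 1])
        peak_rows.append(
            {
                "year": year,
                "max_mean": mx.mean(),
                "max_lo": np.percentile(mx, 2.5),
                "max_hi": np.percentile(mx, 97.5),
                "day_mean": am.mean(),
                "day_lo": np.percentile(am, 2.5),
                "day_hi": np.percentile(am, 97.5),
                "at_edge_frac": peaks[:, 2].mean(),
            }
        )
    return pd.concat(curve_rows, ignore_index=True), pd.DataFrame(peak_rows)


def max_temp_trend(values: np.ndarray, years: np.ndarray) -> dict:
    """OLS trend of a yearly quantity on year: slope, decadal rate, F-test, R^2."""
    values = np.asarray(values, float)
    years = np.asarray(years, float)
    if len(values) < 3:
        raise ModelError("trend needs at least 3 years")
    res = stats.linregress(years, values)
    n = len(values)
    resid = values - (res.intercept + res.slope * years)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((values - values.mean()) ** 2))
    ssr = sst - sse
    F = (ssr / 1) / (sse / (n - 2)) if sse > 0 else np.inf
    if sst == 0:
        F, r2 = 0.0, 0.0
    else:
        r2 = ssr / sst
    return {
        "slope": float(res.slope),
        "decadal": float(res.slope * 10),
        "intercept": float(res.intercept),
        "stderr": float(res.stderr),
        "F": float(F),
        "df": (1, n - 2),
        "p_value": float(res.pvalue),
        "r2": float(r2),
        "n": n,
    }
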
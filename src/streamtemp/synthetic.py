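"""Synthetic multi-site daily air/water/flow series with known ground truth.

The generator emulates a small headwater network observed for many years: one
regional air-temperature series (annual sinusoid plus AR(1) anomalies), a
seasonal log-normal relative-discharge series, and water temperature produced
by the package's own hierarchical model inside each site-year's true
synchronization window.  Outside the window, water decouples from air and
relaxes toward a near-freezing floor, reproducing the flat winter water /
free-swinging winter air contrast of real logger records.  Whole missing
site-years, within-year gaps and random missingness can be imposed on the
water series, with the mask returned for exact inversion.

Every draw is deterministic given the master seed, which is split per
component (air / flow / water / windows / missingness).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .model import ModelParams, Standardization, build_covariates

DEFAULT_SITES = ("WB", "OL", "OS", "IL")

# seed-stream component codes
_AIR, _FLOW, _WATER, _WINDOWS, _MISSING = range(5)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class Mask:
    """One missingness instruction for the water series.

    kind "site_year": drop all water for (site, year).
    kind "range": drop water for (site, year) between start_doy and end_doy
    inclusive.
    kind "random": drop a fraction of currently-observed water days, over the
    whole table or restricted to site/year when given.
    """

    kind: str
    site: str | None = None
    year: int | None = None
    start_doy: int | None = None
    end_doy: int | None = None
    fraction: float | None = None


def default_true_params(
    sites: Sequence[str] = DEFAULT_SITES,
    years: Sequence[int] = (),
    M: np.ndarray | None = None,
    alpha: float = 15.1,
) -> ModelParams:
    """True parameters mirroring posterior means from a long-term four-stream field study.

    Air-temperature effects 1.52 / 0.20 / 0.15 (lags 0-2), flow 0.36, a small
    negative air x flow interaction, site offsets -0.50 / +0.59 / -0.54
    relative to the mainstem, AR mean 0.79 with little site variation, and
    residual sd 0.77.  The year-level cubic hyper-means default to the
    synchronization-consistent cubic (water tracking the seasonal air cycle
    inside the window); Sigma allows warm/cool years of roughly +/-1 degC.
    """
    n_sites = len(sites)
    beta = np.array(
        [1.52, 0.20, 0.15, 0.36, -0.10, -0.50, 0.59, -0.54, 0.05, -0.03, 0.04][: 11]
    )
    if M is None:
        M = np.array([0.0, 0.5, -5.0, -0.5])
    Sigma = np.diag([0.5, 0.3, 0.3, 0.2]) ** 2
    years = tuple(int(y) for y in years)
    return ModelParams(
        alpha=alpha,
        beta=beta,
        B=np.empty((0, 4)),  # sentinel: drawn at generation time unless preset
        b_years=years,
        M=M,
        Sigma=Sigma,
        delta=np.full(n_sites, 0.79),
        mu_delta=0.79,
        sd_delta=0.05,
        sd=0.77,
    )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the field setting: 4 sites, 15 years, a 9 degC mean /
    14 degC amplitude air sinusoid peaking in late July with AR(1) anomalies,
    weakly seasonal log-flow, true windows near doy 105-290 drifting wider
    (spring -1.61 d/yr, fall +1.33 d/yr) with ~5 d site-year jitter, and
    missingness patterned on real logger deployments (tributaries absent in
    early years, occasional within-year gaps).
    """

    sites: tuple = DEFAULT_SITES
    years: tuple = tuple(range(1999, 2014))
    air_mean: float = 9.0
    air_amp: float = 14.0
    air_phase: float = 110.0  # sinusoid peaks ~91 days later (late July)
    air_noise_sd: float = 3.5  # annual-mean marginal sd of the AR(1) anomaly
    air_noise_ar: float = 0.6
    air_noise_seasonal_amp: float = 0.3  # anomalies ~2x larger midwinter than midsummer
    site_air_offsets: tuple | None = None  # one shared regional series by default
    flow_log_mean: float = 0.0
    flow_log_seasonal_amp: float = 0.4  # peaks in spring (doy ~100)
    flow_log_sd: float = 0.5
    flow_log_ar: float = 0.95  # day-to-day discharge persistence
    true_params: ModelParams | None = None
    sync_window_true: dict | None = None  # (site, year) -> (spring_day, fall_day)
    spring_base: float = 105.0
    fall_base: float = 290.0
    spring_trend: float = -1.61  # d/yr
    fall_trend: float = 1.33  # d/yr
    window_jitter_sd: float = 5.0
    edge_water_floor: float = 6.0  # in-window mean water never drops below this
    air_coupling: float = 0.75  # steady-state degC water per degC air inside windows
    winter_floor: float = 0.0  # winter water bounded at freezing; 0 degC days are
    winter_relax_rate: float = 0.15  # invalid for the temperature index
    spring_ramp_days: int = 12  # continuous snowmelt-season ramp up to each window
    year_effect_trend: float = 0.063  # degC/yr drift of the yearly intercept
    winter_air_coupling: float = 0.2
    winter_noise_sd: float = 0.1
    missingness: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not self.years:
            raise SyntheticError("years list must be non-empty")
        if self.flow_log_sd < 0:
            raise SyntheticError("flow_log_sd must be >= 0")
        if not -1 < self.air_noise_ar < 1:
            raise SyntheticError("air_noise_ar must lie strictly in (-1, 1)")
        if self.winter_floor < 0:
            raise SyntheticError("winter_floor must be >= 0")
        if self.sync_window_true is None:
            self.sync_window_true = self._default_windows()
        for (s, y), (sp, fa) in self.sync_window_true.items():
            if not (1 <= sp < fa <= 366):
                raise SyntheticError(f"invalid window {sp}..{fa} for {(s, y)}")
        if self.true_params is None:
            M, alpha = self._synchronized_cubic()
            self.true_params = default_true_params(self.sites, self.years, M=M, alpha=alpha)
        if not np.all(np.abs(self.true_params.delta) < 1):
            raise SyntheticError("true AR coefficients must lie strictly in (-1, 1)")

    def _default_windows(self) -> dict:
        rng = np.random.default_rng([int(self.seed) % (2**31), _WINDOWS])
        mid = np.mean(self.years)
        out = {}
        for s in self.sites:
            for y in self.years:
                sp = self.spring_base + self.spring_trend * (y - mid) + rng.normal(0, self.window_jitter_sd)
                fa = self.fall_base + self.fall_trend * (y - mid) + rng.normal(0, self.window_jitter_sd)
                sp = int(np.clip(round(sp), 32, 170))
                fa = int(np.clip(round(fa), 200, 350))
                out[(s, y)] = (sp, fa)
        return out

    def generation_std_constants(self) -> tuple[float, float]:
        """(air_center, air_scale) used on the generation side.

        Air is centered on its seasonal in-window mean.  The scale is chosen
        so that the fixed lag-0..2 air coefficients (1.52 + 0.20 + 0.15 on
        the standardized scale) sum to ``air_coupling`` degC of water per
        degC of air — the synchronization premise: inside the window, slow
        air excursions transfer almost fully to water.  The coefficient
        *values* are a scale convention; the coupling is the physical choice.
        """
        day_min = min(w[0] for w in self.sync_window_true.values())
        day_max = max(w[1] for w in self.sync_window_true.values())
        airm = air_seasonal_mean(self, np.arange(day_min, day_max + 1, dtype=float))
        scale = (1.52 + 0.20 + 0.15) / self.air_coupling
        return float(airm.mean()), float(scale)

    def _synchronized_cubic(self, alpha: float = 15.1) -> tuple[np.ndarray, float]:
        """Cubic hyper-means that make in-window water track the air cycle.

        Synchronization means the temperature index (water - air)/water sits
        near 0 throughout the window, so the expected water temperature must
        follow the seasonal air mean — bounded below by ``edge_water_floor``,
        since stream water holds a few degrees above freezing air at the
        window edges.  Solving omega(d) = target(d) for the cubic (air on the
        generation standardization scale, flow at its mean) and folding the
        fitted intercept into alpha keeps the model's M[0] = 0 convention.
        """
        day_min = min(w[0] for w in self.sync_window_true.values())
        day_max = max(w[1] for w in self.sync_window_true.values())
        d = np.arange(day_min, day_max + 1, dtype=float)
        airm = air_seasonal_mean(self, d)
        c, s = self.generation_std_constants()
        sstd = (airm - c) / s
        air_effect = (1.52 + 0.20 + 0.15) * sstd  # lag-0..2 air coefficients
        target = np.maximum(airm, self.edge_water_floor) - alpha - air_effect
        u = 2.0 * (d - day_min) / (day_max - day_min) - 1.0
        U = np.column_stack([np.ones_like(u), u, u**2, u**3])
        coef, *_ = np.linalg.lstsq(U, target, rcond=None)
        M = coef.copy()
        M[0] = 0.0
        return M, alpha + float(coef[0])

    def rng(self, component: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), component])


def default_missingness(config: SyntheticConfig) -> tuple[Mask, ...]:
    """Missingness patterned on the real deployment: tributaries start late,
    the mainstem skips two mid-study years, plus a few within-year gaps."""
    sites, years = config.sites, sorted(config.years)
    masks: list[Mask] = []
    for s in sites[1:]:
        for y in years[: min(4, max(0, len(years) - 2))]:
            masks.append(Mask("site_year", site=s, year=y))
    if len(years) >= 10:
        masks.append(Mask("site_year", site=sites[0], year=years[8]))
        masks.append(Mask("site_year", site=sites[0], year=years[10]))
        masks.append(Mask("range", site=sites[0], year=years[9], start_doy=100, end_doy=200))
        if len(sites) > 2:
            masks.append(Mask("range", site=sites[2], year=years[6], start_doy=140, end_doy=260))
    return tuple(masks)


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------


def _date_grid(years: Sequence[int]) -> pd.DataFrame:
    dates = pd.date_range(f"{min(years)}-01-01", f"{max(years)}-12-31", freq="D")
    dates = dates[np.isin(dates.year, list(years))]
    return pd.DataFrame(
        {"date": dates, "year": dates.year.astype(int), "doy": dates.dayofyear.astype(int)}
    )


def air_seasonal_mean(config: SyntheticConfig, doy: np.ndarray) -> np.ndarray:
    """Closed-form annual cycle: mean + amp * sin(2*pi*(doy - phase)/365.25)."""
    return config.air_mean + config.air_amp * np.sin(
        2 * np.pi * (np.asarray(doy, float) - config.air_phase) / 365.25
    )


def generate_air(config: SyntheticConfig) -> pd.DataFrame:
    """Regional air series shared by all sites (plus optional fixed offsets).

    Anomalies follow a stationary AR(1) with marginal sd ``air_noise_sd`` and
    lag-1 correlation ``air_noise_ar``, continuous across year boundaries.
    """
    grid = _date_grid(config.years)
    n = len(grid)
    rng = config.rng(_AIR)
    rho, sd = config.air_noise_ar, config.air_noise_sd
    if sd > 0:
        # winter-amplified anomaly scale (slowly varying, so the marginal sd
        # of the AR(1) tracks sd_day closely)
        doy = grid["doy"].to_numpy(float)
        sd_day = sd * (
            1.0
            + config.air_noise_seasonal_amp
            * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
        )
        innov = rng.standard_normal(n) * sd_day * np.sqrt(1 - rho**2)
        innov[0] = rng.normal(0, sd_day[0])
        noise = lfilter([1.0], [1.0, -rho], innov)
    else:
        noise = np.zeros(n)
    regional = air_seasonal_mean(config, grid["doy"].to_numpy()) + noise
    offsets = config.site_air_offsets or tuple(0.0 for _ in config.sites)
    frames = []
    for s, off in zip(config.sites, offsets):
        f = grid.copy()
        f.insert(0, "site", s)
        f["airT"] = regional + off
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def generate_flow(config: SyntheticConfig) -> pd.DataFrame:
    """Strictly positive relative discharge: exp(seasonal log-mean + noise)."""
    grid = _date_grid(config.years)
    rng = config.rng(_FLOW)
    doy = grid["doy"].to_numpy(float)
    log_mean = config.flow_log_mean + config.flow_log_seasonal_amp * np.sin(
        2 * np.pi * (doy - 10.0) / 365.25
    )
    frames = []
    rho = config.flow_log_ar
    n = len(grid)
    for s in config.sites:
        if config.flow_log_sd > 0:
            innov = rng.normal(0, config.flow_log_sd * np.sqrt(1 - rho**2), n)
            innov[0] = rng.normal(0, config.flow_log_sd)
            noise = lfilter([1.0], [1.0, -rho], innov)
        else:
            noise = np.zeros(n)
        f = grid.copy()
        f.insert(0, "site", s)
        f["flow"] = np.exp(log_mean + noise)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery: true parameters (with the year
    effects actually drawn), true windows, the standardization used during
    generation, latent linear predictors, and any applied mask."""

    params: ModelParams
    windows: dict
    std: Standardization
    latent: pd.DataFrame  # site, date, omega, resid, in_window
    masks: tuple = ()
    mask_record: pd.DataFrame | None = None

    def windows_frame(self) -> pd.DataFrame:
        rows = [
            {"site": s, "year": y, "spring_day": sp, "fall_day": fa}
            for (s, y), (sp, fa) in sorted(self.windows.items())
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "alpha": p.alpha,
                "beta": p.beta,
                "B": p.B,
                "b_years": list(p.b_years),
                "M": p.M,
                "Sigma": p.Sigma,
                "delta": p.delta,
                "mu_delta": p.mu_delta,
                "sd_delta": p.sd_delta,
                "sd": p.sd,
            },
            "windows": {f"{s}|{y}": [sp, fa] for (s, y), (sp, fa) in sorted(self.windows.items())},
            "standardization": self.std.to_dict(),
            "masks": [vars(m) for m in self.masks],
        }


def generate_water(
    air: pd.DataFrame, flow: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Water temperature from the model's own generative process.

    Inside each true window the series follows the hierarchical AR(1) model
    with the true parameters (day 1 of a window takes the no-AR path; air
    lags come from the year-round air series).  Outside, water relaxes toward
    max(winter_floor, winter_air_coupling * airT) at ``winter_relax_rate`` per
    day with small noise, so air and water visibly decouple.
    """
    df = air.merge(flow[["site", "date", "flow"]], on=["site", "date"], how="inner")
    if len(df) != len(air):
        raise SyntheticError("air and flow must cover identical site/day grids")
    df = df.sort_values(["site", "date"]).reset_index(drop=True)

    params = config.true_params
    windows = config.sync_window_true
    rng = config.rng(_WATER)

    # draw year effects from the hyperdistribution unless preset; the yearly
    # intercept drifts upward at the study's observed warming rate
    B = np.asarray(params.B, float)
    if B.size == 0:
        years_arr = np.array(params.b_years, float)
        B = rng.multivariate_normal(params.M, params.Sigma, size=len(params.b_years))
        B[:, 0] += config.year_effect_trend * (years_arr - years_arr.mean())
    params = replace(params, B=B)

    # generation-time standardization from in-window covariates
    keys = list(zip(df["site"], df["year"]))
    doy = df["doy"].to_numpy()
    in_win = np.array(
        [k in windows and windows[k][0] <= d <= windows[k][1] for k, d in zip(keys, doy)]
    )
    span = [w for w in windows.values()]
    air_center, air_scale = config.generation_std_constants()
    std = Standardization(
        mode="standard",
        air_center=air_center,
        air_scale=air_scale,
        flow_center=float(np.log(df.loc[in_win, "flow"]).mean()),
        flow_scale=float(np.log(df.loc[in_win, "flow"]).std(ddof=0)) or 1.0,
        log_flow=True,
        day_min=float(min(w[0] for w in span)),
        day_max=float(max(w[1] for w in span)),
    )

    g = df.groupby("site", sort=False)
    work = df.assign(
        airT_lag1=g["airT"].shift(1).fillna(df["airT"]).to_numpy(),
        airT_lag2=g["airT"].shift(2).fillna(df["airT"]).to_numpy(),
    )
    Xf, Xy = build_covariates(work, std, config.sites)
    theta = params.theta_fixed()
    year_of = df["year"].to_numpy()
    b_index = {y: j for j, y in enumerate(params.b_years)}
    omega_all = Xf @ theta + np.einsum(
        "ij,ij->i", Xy, B[[b_index[y] for y in year_of]]
    )

    water = np.full(len(df), np.nan)
    omega_store = np.full(len(df), np.nan)
    resid_store = np.full(len(df), np.nan)

    for s in config.sites:
        rows = np.where(df["site"].to_numpy() == s)[0]
        s_idx = config.sites.index(s)
        delta = float(params.delta[s_idx])
        w = np.full(len(rows), np.nan)
        inw = in_win[rows]
        # in-window segments: omega + AR(1) residuals, restarted per window
        padded = np.concatenate([[False], inw, [False]])
        edges = np.diff(padded.astype(int))
        seg_starts = np.where(edges == 1)[0]
        seg_ends = np.where(edges == -1)[0] - 1
        for a, b in zip(seg_starts, seg_ends):
            m = b - a + 1
            if params.sd > 0:
                e = lfilter([1.0], [1.0, -delta], rng.normal(0, params.sd, m))
            else:
                e = np.zeros(m)
            w[a : b + 1] = omega_all[rows[a : b + 1]] + e
            resid_store[rows[a : b + 1]] = e
        omega_store[rows[inw]] = omega_all[rows[inw]]
        # pre-window ramp: the spring transition is continuous, so the last
        # days before each window blend toward the window-start predictor
        T = config.spring_ramp_days
        blend = np.zeros(len(rows))
        blend_val = np.zeros(len(rows))
        for a in seg_starts:
            for g in range(1, T + 1):
                i = a - g
                if i < 0 or inw[i]:
                    break
                blend[i] = (T - g + 1) / (T + 1)
                blend_val[i] = omega_all[rows[a]]
        # winter relaxation outside windows (sequential)
        air_s = df["airT"].to_numpy()[rows]
        k = config.winter_relax_rate
        for i in range(len(rows)):
            if inw[i]:
                continue
            target = max(config.winter_floor, config.winter_air_coupling * air_s[i])
            target = (1 - blend[i]) * target + blend[i] * blend_val[i]
            prev = w[i - 1] if i > 0 and np.isfinite(w[i - 1]) else target
            noise = rng.normal(0, config.winter_noise_sd) if config.winter_noise_sd > 0 else 0.0
            w[i] = max(config.winter_floor, prev + k * (target - prev) + noise)
        water[rows] = w

    out = df.copy()
    out["waterT"] = water
    latent = df[["site", "date", "year", "doy"]].copy()
    latent["omega"] = omega_store
    latent["resid"] = resid_store
    latent["in_window"] = in_win
    truth = SyntheticTruth(params=params, windows=dict(windows), std=std, latent=latent)
    return out[["site", "date", "year", "doy", "airT", "waterT", "flow"]], truth


def apply_missingness(
    df: pd.DataFrame, masks: Sequence[Mask], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask water values (air and flow are never masked).

    Returns (masked table, mask record).  The record lists every (site, date)
    whose water value was removed together with the removed value, so tests
    can invert the mask exactly.  Random-fraction masks remove exactly
    round(fraction * n_eligible) currently-observed days, reproducibly.
    """
    out = df.copy().reset_index(drop=True)
    rng = np.random.default_rng([int(seed) % (2**31), _MISSING])
    removed = []
    for mask in masks:
        if mask.kind == "site_year":
            sel = (out["site"] == mask.site) & (out["year"] == mask.year)
            if not sel.any():
                raise SyntheticError(f"mask references absent site-year {mask.site}/{mask.year}")
        elif mask.kind == "range":
            sel = (out["site"] == mask.site) & (out["year"] == mask.year)
            if not sel.any():
                raise SyntheticError(f"mask references absent site-year {mask.site}/{mask.year}")
            sel &= (out["doy"] >= mask.start_doy) & (out["doy"] <= mask.end_doy)
            if not sel.any():
                raise SyntheticError(f"day range {mask.start_doy}..{mask.end_doy} outside data")
        elif mask.kind == "random":
            sel = out["waterT"].notna()
            if mask.site is not None:
                sel &= out["site"] == mask.site
            if mask.year is not None:
                sel &= out["year"] == mask.year
            idx = np.where(sel.to_numpy())[0]
            n_drop = int(round(mask.fraction * len(idx)))
            chosen = rng.choice(idx, size=n_drop, replace=False)
            sel = pd.Series(False, index=out.index)
            sel.iloc[chosen] = True
        else:
            raise SyntheticError(f"unknown mask kind {mask.kind!r}")
        sel &= out["waterT"].notna()
        for i in np.where(sel.to_numpy())[0]:
            removed.append(
                {"site": out["site"].iat[i], "date": out["date"].iat[i], "waterT": out["waterT"].iat[i]}
            )
        out.loc[sel, "waterT"] = np.nan
    record = pd.DataFrame(removed, columns=["site", "date", "waterT"])
    return out, record


def simulate(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Full generative pass: air + flow -> water -> missingness."""
    air = generate_air(config)
    flow = generate_flow(config)
    data, truth = generate_water(air, flow, config)
    masked, record = apply_missingness(data, config.missingness, seed=config.seed)
    truth.masks = tuple(config.missingness)
    truth.mask_record = record
    return masked, truth
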
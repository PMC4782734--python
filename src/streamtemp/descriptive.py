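"""Descriptive diagnostics: pooled seasonal spline, cumulative residual
curves per site-year, and between-site daily water-temperature correlations.

The spline is a penalized smoothing spline of water temperature on day of
year, pooled over all sites and years, with the penalty chosen by generalized
cross-validation.  Cumulative residual curves (running sum of observed minus
spline) read like climate anomaly plots: a year ending above zero ran warm,
below zero ran cool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


class DescriptiveError(ValueError):
    pass


class SeasonalSpline:
    """Evaluable penalized smooth of water temperature on day of year.

    Fit on per-doy means weighted by observation counts (duplicate abscissae
    are not accepted by the smoother); ``lam=None`` selects the penalty by
    GCV.
    """

    def __init__(self, doy: np.ndarray, waterT: np.ndarray, lam: float | None = None,
                 min_obs: int = 50, min_distinct: int = 100):
        doy = np.asarray(doy, float)
        waterT = np.asarray(waterT, float)
        ok = np.isfinite(doy) & np.isfinite(waterT)
        doy, waterT = doy[ok], waterT[ok]
        distinct = np.unique(doy)
        if len(waterT) < min_obs or len(distinct) < min_distinct:
            raise DescriptiveError(
                f"need >= {min_obs} observations over >= {min_distinct} distinct days "
                f"(got {len(waterT)} over {len(distinct)})"
            )
        grp = pd.DataFrame({"doy": doy, "w": waterT}).groupby("doy")["w"]
        means = grp.mean()
        counts = grp.size()
        self._spline = make_smoothing_spline(
            means.index.to_numpy(), means.to_numpy(),
            w=counts.to_numpy(float), lam=lam,
        )
        self.doy_range = (float(distinct.min()), float(distinct.max()))
        self.n_obs = int(len(waterT))

    def __call__(self, doy):
        return self._spline(np.asarray(doy, float))

    def curve(self, step: float = 1.0) -> pd.DataFrame:
        g = np.arange(self.doy_range[0], self.doy_range[1] + step / 2, step)
        return pd.DataFrame({"doy": g, "fitted": self(g)})


def seasonal_spline(df: pd.DataFrame, lam: float | None = None) -> SeasonalSpline:
    """Fit the pooled seasonal spline to all observed water temperatures."""
    obs = df.dropna(subset=["waterT"])
    return SeasonalSpline(obs["doy"].to_numpy(), obs["waterT"].to_numpy(), lam=lam)


def cumulative_residuals(df: pd.DataFrame, spline: SeasonalSpline) -> pd.DataFrame:
    """Per site-year running sum of (observed - spline) over day of year.

    Missing days contribute 0 to the running sum and are flagged.  Curves
    start at 0 (the first row is the first day's cumulative value).
    """
    rows = []
    for (site, year), g in df.groupby(["site", "year"], sort=True):
        g = g.sort_values("doy")
        resid = g["waterT"].to_numpy(float) - spline(g["doy"].to_numpy())
        observed = np.isfinite(resid)
        contrib = np.where(observed, resid, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "site": site,
                    "year": int(year),
                    "doy": g["doy"].to_numpy(),
                    "cumres": np.cumsum(contrib),
                    "observed": observed,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def site_correlations(df: pd.DataFrame, min_shared_days: int = 30) -> pd.DataFrame:
    """Pearson correlation of daily water temperature between sites.

    Computed on pairwise-complete days; pairs sharing fewer than
    ``min_shared_days`` observed days are reported as NaN.  Symmetric with a
    unit diagonal.
    """
    wide = df.pivot_table(index="date", columns="site", values="waterT", aggfunc="first")
    corr = wide.corr(method="pearson", min_periods=min_shared_days)
    np.fill_diagonal(corr.values, 1.0)
    return corr
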
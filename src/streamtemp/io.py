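"""Canonical daily-series table: schema, validation, read/write.

The canonical table is a plain CSV with one row per site-day:

    site, date (ISO-8601), year, doy (1-based), airT (degC),
    waterT (degC, may be missing), flow (relative discharge, may be missing)

Missing values are written as ``NA`` and accepted as ``NA`` or an empty field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ["site", "date", "year", "doy", "airT", "waterT", "flow"]

#: sanity bounds, configurable via read_canonical arguments
AIR_BOUNDS = (-50.0, 50.0)
WATER_BOUNDS = (-5.0, 40.0)


class CanonicalError(ValueError):
    """Raised when a canonical table violates its schema invariants."""


def validate_canonical(
    df: pd.DataFrame,
    air_bounds: tuple[float, float] = AIR_BOUNDS,
    water_bounds: tuple[float, float] = WATER_BOUNDS,
) -> None:
    """Check schema invariants, raising :class:`CanonicalError` with row numbers."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CanonicalError(f"missing required columns: {missing}")

    dates = pd.to_datetime(df["date"], errors="coerce")
    bad = df.index[dates.isna()]
    if len(bad):
        raise CanonicalError(f"malformed dates at rows {list(bad[:10])}")

    dup = df.duplicated(subset=["site", "date"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["site", "date"]].head(10).to_dict("records")
        raise CanonicalError(f"duplicate (site, date) pairs: {pairs}")

    doy = dates.dt.dayofyear
    bad = df.index[(df["doy"].to_numpy() != doy.to_numpy())]
    if len(bad):
        raise CanonicalError(f"doy inconsistent with date at rows {list(bad[:10])}")
    bad = df.index[(df["year"].to_numpy() != dates.dt.year.to_numpy())]
    if len(bad):
        raise CanonicalError(f"year inconsistent with date at rows {list(bad[:10])}")

    air = df["airT"].to_numpy(dtype=float)
    bad = df.index[(air < air_bounds[0]) | (air > air_bounds[1]) | ~np.isfinite(air)]
    if len(bad):
        raise CanonicalError(f"airT outside {air_bounds} at rows {list(bad[:10])}")

    water = df["waterT"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = df.index[(water < water_bounds[0]) | (water > water_bounds[1])]
    if len(bad):
        raise CanonicalError(f"waterT outside {water_bounds} at rows {list(bad[:10])}")

    flow = df["flow"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = df.index[flow <= 0]
    if len(bad):
        raise CanonicalError(f"non-positive flow at rows {list(bad[:10])}")


def read_canonical(path: str | Path, **bounds) -> pd.DataFrame:
    """Read and validate a canonical CSV.

    Returns a DataFrame with ``date`` parsed to datetime64, ``waterT``/``flow``
    as floats with NaN for missing, sorted by (site, date).
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    validate_canonical(df, **bounds)
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["year"].astype(int)
    df["doy"] = df["doy"].astype(int)
    for col in ("airT", "waterT", "flow"):
        df[col] = df[col].astype(float)
    return df.sort_values(["site", "date"]).reset_index(drop=True)


def write_canonical(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical CSV with ``NA`` for missing values (ISO dates)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[COLUMNS].to_csv(path, index=False, na_rep="NA", float_format="%.6g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
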
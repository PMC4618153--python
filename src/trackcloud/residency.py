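"""Residency time along best tracks and habitat annotation.

Residency time at a location is the cumulative time the bird spends
within a fixed-radius circle (default 45 km, roughly one mean daily
displacement) around that location, restricted to a time window (default
±15 days, i.e. a 30-day constraint) so that re-crossings months later on
the return trip do not inflate it.  On a daily track this is a windowed
day count:

    residency(i) = #{ j : |t_j - t_i| <= time_constraint / 2
                          and  d(p_j, p_i) <= radius }  days

which always includes the location itself (residency >= 1 day) and is
bounded by the window length (time_constraint + 1 days).  High-residency
locations — intensive search — are those at or above each individual's
upper-quartile residency.

Habitat covariates are annotated by nearest raster cell, matched by
calendar month, except that chlorophyll-a for first-week locations uses
the previous month's composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial.distance import cdist

from .simulate import HABITAT_VARS, TrackCloud

__all__ = ["ResidencyConfig", "residency_time", "annotate_habitat",
           "transform_covariates"]


@dataclass(frozen=True)
class ResidencyConfig:
    radius_km: float = 45.0
    time_constraint_days: float = 30.0
    high_quantile: float = 0.75

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError("radius_km must be > 0")
        if self.time_constraint_days <= 0:
            raise ValueError("time_constraint_days must be > 0")
        if not 0.0 < self.high_quantile < 1.0:
            raise ValueError("high_quantile must be in (0, 1)")


def _track_frame(track) -> pd.DataFrame:
    if isinstance(track, TrackCloud):
        return pd.DataFrame({"bird_id": track.bird_id, "date": track.dates,
                             "x": track.best_x, "y": track.best_y})
    df = pd.DataFrame(track)
    required = {"date", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"track frame needs columns {sorted(required)}")
    if "bird_id" not in df.columns:
        df["bird_id"] = "track"
    return df.sort_values("date").reset_index(drop=True)


def residency_time(track, config: ResidencyConfig = ResidencyConfig()) -> pd.DataFrame:
    """Windowed residency profile of a daily best track.

    ``track`` is a TrackCloud (replicate 0 is used) or a frame with
    columns date/x/y.  Returns one row per location with
    ``residency_days`` and the upper-quantile ``is_high_residency`` flag
    (linear-interpolation quantile; ties flagged inclusively, >=).
    """
    df = _track_frame(track)
    n = len(df)
    if n < 2:
        raise ValueError("residency_time requires a track of at least 2 points")
    t = pd.DatetimeIndex(df["date"])
    days = (t - t[0]).days.to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)
    dist = cdist(xy, xy)
    dt = np.abs(days[:, None] - days[None, :])
    within = (dist <= config.radius_km) & (dt <= config.time_constraint_days / 2.0)
    residency = within.sum(axis=1).astype(float)  # days (daily sampling)
    threshold = float(np.quantile(residency, config.high_quantile))
    out = df.copy()
    out["residency_days"] = residency
    out["is_high_residency"] = residency >= threshold
    return out


def annotate_habitat(profile: pd.DataFrame, habitat: xr.Dataset,
                     variables=HABITAT_VARS) -> pd.DataFrame:
    """Annotate each location with habitat covariates by nearest raster cell.

    Covariates are matched by the location's calendar month, except
    chlorophyll-a, where locations from the first week of a month borrow
    the previous month's composite.  Locations outside the raster extent
    get missing values; the rows are retained.
    """
    out = profile.copy()
    dates = pd.DatetimeIndex(out["date"])
    month = dates.strftime("%Y-%m")
    prev = (dates - pd.offsets.MonthEnd(1)).strftime("%Y-%m")  # previous month label
    chla_month = np.where(dates.day <= 7, prev, month)

    xs = out["x"].to_numpy(dtype=float)
    ys = out["y"].to_numpy(dtype=float)
    xc = habitat.x.values
    yc = habitat.y.values
    half = float(habitat.attrs.get("cell_km", float(np.diff(xc).mean()))) / 2.0
    inside = ((xs >= xc.min() - half) & (xs <= xc.max() + half)
              & (ys >= yc.min() - half) & (ys <= yc.max() + half))
    jx = _nearest_index(xc, xs)
    iy = _nearest_index(yc, ys)

    month_labels = [str(m) for m in np.atleast_1d(habitat.month.values)]
    month_pos = {m: k for k, m in enumerate(month_labels)}
    for var in variables:
        if var not in habitat:
            raise ValueError(f"habitat raster set lacks variable '{var}'")
        labels = chla_month if var == "chla" else month
        im = np.array([month_pos.get(m, -1) for m in labels])
        ok = inside & (im >= 0)
        cube = habitat[var].transpose("month", "y", "x").values
        vals = np.full(len(out), np.nan)
        vals[ok] = cube[im[ok], iy[ok], jx[ok]]
        out[var] = vals
    out["month"] = dates.month
    return out


def _nearest_index(coords: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Index of the nearest coordinate for each value (coords ascending)."""
    idx = np.searchsorted(coords, values)
    idx = np.clip(idx, 1, len(coords) - 1)
    left = np.abs(values - coords[idx - 1]) <= np.abs(values - coords[idx])
    return np.where(left, idx - 1, idx)


def transform_covariates(samples: pd.DataFrame) -> pd.DataFrame:
    """Build the model design table with the field-standard transforms.

    Response: log residency time.  Right-skewed chl a is log transformed;
    distance-to-eddy and bathymetric slope are square-root transformed;
    everything else enters untransformed.  Rows with nonpositive chl a
    are an error (named by row label); missing covariates pass through
    as missing for the fitting stage to drop listwise.
    """
    df = samples.copy()
    bad = df.index[df["chla"].notna() & (df["chla"] <= 0)]
    if len(bad):
        raise ValueError(f"nonpositive chla at row {bad[0]}: log transform undefined")
    for col in ("d2eddy", "slope"):
        neg = df.index[df[col].notna() & (df[col] < 0)]
        if len(neg):
            raise ValueError(f"negative {col} at row {neg[0]}: sqrt transform undefined")
    if (df["residency_days"] <= 0).any():
        raise ValueError("residency_days must be positive for the log response")
    design = pd.DataFrame({
        "bird_id": df["bird_id"],
        "log_residency": np.log(df["residency_days"].astype(float)),
        "sst": df["sst"],
        "depth": df["depth"],
        "sqrt_slope": np.sqrt(df["slope"]),
        "ssh": df["ssh"],
        "eke": df["eke"],
        "sqrt_d2eddy": np.sqrt(df["d2eddy"]),
        "d2hill": df["d2hill"],
        "log_chla": np.log(df["chla"]),
        "wind": df["wind"],
    })
    for extra in ("region", "month", "date"):
        if extra in df.columns:
            design[extra] = df[extra]
    return design
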
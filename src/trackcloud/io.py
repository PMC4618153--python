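"""Text-format IO: track-cloud CSV, ecoregion GeoJSON, habitat-raster CSV.

Track CSV columns: ``bird_id, colony, sex, year, date, replicate_id,
x_km, y_km`` (ISO-8601 dates, projected km).  ``read_tracks`` validates
the track-cloud invariants — replicate 0 present, identical date range
per replicate, gapless daily dates — and reports the offending line and
field for malformed rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .simulate import TrackCloud

__all__ = ["write_tracks", "read_tracks", "write_ecoregions", "read_ecoregions",
           "write_habitat", "read_habitat"]

TRACK_COLUMNS = ["bird_id", "colony", "sex", "year", "date", "replicate_id",
                 "x_km", "y_km"]


def write_tracks(clouds, path) -> None:
    """Write a list of TrackClouds to tidy CSV (one row per point)."""
    frames = [c.to_frame() for c in clouds]
    df = pd.concat(frames, ignore_index=True)
    df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    # %.17g keeps float64 exact so read(write(x)) == x
    df[TRACK_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def _convert(df: pd.DataFrame, col: str, converter, kind: str) -> pd.Series:
    raw = df[col]
    out = converter(raw)
    bad = out.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.values)[0]) + 2  # header is line 1
        raise ValueError(f"malformed row at line {line}: field '{col}' is not "
                         f"a valid {kind} ({raw.iloc[int(np.flatnonzero(bad.values)[0])]!r})")
    if raw.isna().any():
        line = int(np.flatnonzero(raw.isna().values)[0]) + 2
        raise ValueError(f"malformed row at line {line}: field '{col}' is missing")
    return out


def read_tracks(path) -> list[TrackCloud]:
    """Read a track CSV back into TrackClouds, validating all invariants."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV is missing columns: {missing}")
    df["year"] = _convert(df, "year", lambda s: pd.to_numeric(s, errors="coerce"),
                          "integer").astype(int)
    df["replicate_id"] = _convert(df, "replicate_id",
                                  lambda s: pd.to_numeric(s, errors="coerce"),
                                  "integer").astype(int)
    def _strtod(s: pd.Series) -> pd.Series:
        # float() is correctly rounded; pd.to_numeric can be off by one ulp
        def one(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan
        return s.map(one)

    for col in ("x_km", "y_km"):
        df[col] = _convert(df, col, _strtod, "number").astype(float)
    df["date"] = _convert(df, "date", lambda s: pd.to_datetime(s, errors="coerce",
                                                               format="%Y-%m-%d"),
                          "ISO-8601 date")

    clouds = []
    for (bird, year), g in df.groupby(["bird_id", "year"], sort=True):
        reps = np.sort(g["replicate_id"].unique())
        if reps[0] != 0:
            raise ValueError(f"bird {bird} year {year}: replicate 0 (best track) missing")
        if not np.array_equal(reps, np.arange(len(reps))):
            raise ValueError(f"bird {bird} year {year}: replicate ids are not 0..R "
                             f"(got {reps.tolist()})")
        dates = pd.DatetimeIndex(np.sort(g.loc[g.replicate_id == 0, "date"].unique()))
        if len(dates) > 1:
            deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError(f"bird {bird} year {year}: date gap in daily sequence")
        n_rep, n_days = len(reps), len(dates)
        if len(g) != n_rep * n_days:
            raise ValueError(f"bird {bird} year {year}: replicates do not share an "
                             "identical date range")
        g = g.sort_values(["replicate_id", "date"])
        per_rep_days = g.groupby("replicate_id")["date"].nunique()
        if not (per_rep_days == n_days).all():
            raise ValueError(f"bird {bird} year {year}: replicates do not share an "
                             "identical date range")
        x = g["x_km"].to_numpy().reshape(n_rep, n_days)
        y = g["y_km"].to_numpy().reshape(n_rep, n_days)
        colony = g["colony"].iloc[0]
        sex = g["sex"].iloc[0]
        clouds.append(TrackCloud(bird_id=str(bird), year=int(year), colony=colony,
                                 sex=sex, dates=dates, x=x, y=y))
    return clouds


# ---------------------------------------------------------------------------
# ecoregions

def write_ecoregions(emap, path) -> None:
    """Write an EcoregionMap's polygons to GeoJSON (projected km coordinates)."""
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {"region": name},
         "geometry": mapping(geom)}
        for name, geom in sorted(emap.regions.items())
    ]
    payload = {"type": "FeatureCollection",
               "crs_note": "coordinates are projected km (Lambert azimuthal equal-area)",
               "features": features}
    Path(path).write_text(json.dumps(payload))


def read_ecoregions(path):
    """Read GeoJSON polygons with a 'region' property into an EcoregionMap."""
    from shapely.geometry import shape

    from .ecoregions import EcoregionMap

    payload = json.loads(Path(path).read_text())
    regions = {}
    for feat in payload.get("features", []):
        props = feat.get("properties") or {}
        if "region" not in props:
            raise ValueError("GeoJSON feature lacks a 'region' property")
        regions[str(props["region"])] = shape(feat["geometry"])
    if not regions:
        raise ValueError(f"no region features found in {path}")
    return EcoregionMap(regions=regions)


# ---------------------------------------------------------------------------
# habitat rasters (long-format gridded CSV)

def write_habitat(ds: xr.Dataset, path) -> None:
    """Write a (month, y, x) habitat Dataset as long-format CSV."""
    df = ds.to_dataframe().reset_index()
    df.to_csv(path, index=False)


def read_habitat(path) -> xr.Dataset:
    df = pd.read_csv(path, dtype={"month": str})
    ds = df.set_index(["month", "y", "x"]).to_xarray()
    return ds
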
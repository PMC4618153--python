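"""Biogeographic-province occupancy metrics.

An :class:`EcoregionMap` is a labeled polygon partition of the projected
domain.  Grid cells are assigned to provinces by their center point
(centers exactly on a boundary go to the lexicographically first region);
cells outside every polygon are labeled ``"outside"``.  Per province and
year the module reports the fraction of the province occupied, the mean
bird density over occupied cells, and the share of the total bird
distribution — plus per-bird province counts and monthly
location-weighted province shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .gridding import CellSet, GridSpec, occupied_cells

__all__ = ["EcoregionMap", "synthetic_ecoregions", "assign_cells",
           "region_metrics", "per_bird_region_count", "monthly_region_share",
           "OUTSIDE"]

OUTSIDE = "outside"


@dataclass
class EcoregionMap:
    """Named polygons in projected km, optionally rasterized onto a grid."""

    regions: dict
    grid: GridSpec | None = None
    cell_assignment: dict = field(default_factory=dict)

    def region_of_cells(self, cells) -> list[str]:
        """Region label per cell; unassigned/out-of-domain cells -> 'outside'."""
        return [self.cell_assignment.get(tuple(c), OUTSIDE) for c in cells]

    def n_cells_by_region(self) -> pd.Series:
        return pd.Series(list(self.cell_assignment.values())).value_counts().sort_index()


def synthetic_ecoregions(extent: float = 2800.0) -> EcoregionMap:
    """A fixed eight-province rectangular partition of the study plane.

    Mimics the structure of the North Pacific province set used for
    wintering seabirds: epicontinental seas in the north (the colony sits
    in 'bering'), two subarctic gyres and a coastal downwelling zone in
    the mid-latitudes, and a polar-front band flanked by western/eastern
    boundary-current provinces in the south.
    """
    e = extent
    regions = {
        "okhotsk": box(-e, 400, -1000, e),
        "bering": box(-1000, 400, e, e),
        "gyre_west": box(-e, -1200, 0, 400),
        "gyre_east": box(0, -1200, 1400, 400),
        "alaska_coastal": box(1400, -1200, e, 400),
        "kuroshio": box(-e, -e, -1400, -1200),
        "polar_front": box(-1400, -e, 1400, -1200),
        "california_current": box(1400, -e, e, -1200),
    }
    return EcoregionMap(regions=regions)


def assign_cells(grid: GridSpec, emap: EcoregionMap, bounds=None) -> EcoregionMap:
    """Rasterize the province polygons onto ``grid`` by cell center.

    ``bounds`` (minx, miny, maxx, maxy) defaults to the union of the
    polygon bounds.  Cell centers covered by several polygons (shared
    boundaries) go to the lexicographically first region name.
    """
    for name, geom in emap.regions.items():
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for region '{name}'")
    if bounds is None:
        bs = np.array([g.bounds for g in emap.regions.values()])
        bounds = (bs[:, 0].min(), bs[:, 1].min(), bs[:, 2].max(), bs[:, 3].max())
    minx, miny, maxx, maxy = bounds
    i0, j0 = grid.cell_indices(minx, miny)
    i1, j1 = grid.cell_indices(maxx, maxy)
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    cx = grid.origin[0] + (ii + 0.5) * grid.cell_size
    cy = grid.origin[1] + (jj + 0.5) * grid.cell_size
    pts = shapely.points(cx, cy)

    assignment: dict = {}
    assigned = np.zeros(len(ii), dtype=bool)
    for name in sorted(emap.regions):
        covered = shapely.covers(emap.regions[name], pts) & ~assigned
        for i, j in zip(ii[covered].tolist(), jj[covered].tolist()):
            assignment[(i, j)] = name
        assigned |= covered
    # enumerated domain cells not covered by any polygon are explicit 'outside'
    for i, j in zip(ii[~assigned].tolist(), jj[~assigned].tolist()):
        assignment[(i, j)] = OUTSIDE
    return EcoregionMap(regions=dict(emap.regions), grid=grid,
                        cell_assignment=assignment)


def _cellsets_by_year(clouds_or_cellsets, grid: GridSpec) -> dict:
    """Accept TrackClouds (grouped by year) or a ready dict year -> [CellSet]."""
    if isinstance(clouds_or_cellsets, dict):
        out = clouds_or_cellsets
    else:
        out = {}
        for c in clouds_or_cellsets:
            out.setdefault(c.year, []).append(occupied_cells(c, grid))
    for year, css in out.items():
        for cs in css:
            if cs.grid != grid:
                raise ValueError(f"cell set for year {year} is on a different grid "
                                 "than the ecoregion rasterization")
    return out


def region_metrics(clouds, emap: EcoregionMap, grid: GridSpec | None = None) -> pd.DataFrame:
    """Province-by-year occupancy table.

    Columns: ``pct_region_occupied`` (occupied/total cells in province, %),
    ``mean_occupied_density`` (mean number of birds per occupied cell; 0
    when nothing is occupied), ``pct_bird_distribution`` (share of all
    occupied cells falling in the province, %; sums to 100 across
    provinces plus 'outside').
    """
    if grid is None:
        grid = emap.grid
    if not emap.cell_assignment or emap.grid != grid:
        raise ValueError("emap must be rasterized with assign_cells on the same grid")
    by_year = _cellsets_by_year(clouds, grid)
    n_cells_region = emap.n_cells_by_region()
    region_names = sorted(emap.regions) + [OUTSIDE]

    rows = []
    for year in sorted(by_year):
        cellsets = by_year[year]
        counts: dict = {}
        for cs in cellsets:
            for cell in cs.cells:
                counts[cell] = counts.get(cell, 0) + 1
        occupied = list(counts)
        labels = emap.region_of_cells(occupied)
        lab_arr = np.asarray(labels)
        occ_arr = np.asarray([counts[c] for c in occupied])
        total_occupied = len(occupied)
        for name in region_names:
            in_region = lab_arr == name
            n_occ = int(in_region.sum())
            n_region = int(n_cells_region.get(name, 0))
            rows.append({
                "region": name,
                "year": year,
                "n_region_cells": n_region,
                "n_occupied_cells": n_occ,
                "pct_region_occupied":
                    100.0 * n_occ / n_region if n_region else 0.0,
                "mean_occupied_density":
                    float(occ_arr[in_region].mean()) if n_occ else 0.0,
                "pct_bird_distribution":
                    100.0 * n_occ / total_occupied if total_occupied else 0.0,
            })
    return pd.DataFrame(rows)


def per_bird_region_count(clouds, emap: EcoregionMap, grid: GridSpec | None = None):
    """Distinct provinces (excluding 'outside') intersected by each bird-winter.

    Returns ``(per_bird, summaries)``: a tidy frame with one row per
    bird-winter and mean ± SD summaries by sex and by colony.
    """
    if grid is None:
        grid = emap.grid
    if not emap.cell_assignment or emap.grid != grid:
        raise ValueError("emap must be rasterized with assign_cells on the same grid")
    rows = []
    for c in clouds:
        cs = occupied_cells(c, grid)
        labels = set(emap.region_of_cells(cs.cells)) - {OUTSIDE}
        rows.append({"bird_id": c.bird_id, "year": c.year, "colony": c.colony,
                     "sex": c.sex, "n_regions": len(labels)})
    per_bird = pd.DataFrame(rows)
    summaries = []
    for key in ("sex", "colony"):
        s = per_bird.groupby(key)["n_regions"].agg(["mean", "std", "count"]).reset_index()
        s = s.rename(columns={key: "level"})
        s.insert(0, "group", key)
        summaries.append(s)
    return per_bird, pd.concat(summaries, ignore_index=True)


def monthly_region_share(clouds, emap: EcoregionMap, grid: GridSpec | None = None) -> pd.DataFrame:
    """Location-weighted % of replicate points per province × month × year.

    Shares sum to 100 within each (year, month) across provinces plus
    'outside'.  Months are labeled by calendar month of the location.
    """
    if grid is None:
        grid = emap.grid
    if not emap.cell_assignment or emap.grid != grid:
        raise ValueError("emap must be rasterized with assign_cells on the same grid")
    frames = []
    for c in clouds:
        n_rep, n_days = c.x.shape
        i, j = grid.cell_indices(c.x.ravel(), c.y.ravel())
        frames.append(pd.DataFrame({
            "year": c.year,
            "month": np.tile(c.dates.month.values, n_rep),
            "cell_i": i, "cell_j": j,
        }))
    pts = pd.concat(frames, ignore_index=True)
    lookup = pd.DataFrame(
        [(i, j, r) for (i, j), r in emap.cell_assignment.items()],
        columns=["cell_i", "cell_j", "region"])
    pts = pts.merge(lookup, on=["cell_i", "cell_j"], how="left")
    pts["region"] = pts["region"].fillna(OUTSIDE)
    share = (pts.groupby(["year", "month", "region"], sort=True).size()
             .groupby(level=[0, 1]).transform(lambda s: 100.0 * s / s.sum())
             .rename("pct_locations").reset_index())
    return share
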
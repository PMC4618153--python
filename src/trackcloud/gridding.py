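"""Equal-area gridding of track clouds into occupied-cell sets and densities.

Location uncertainty is propagated by gridding *every* replicate track:
a cell counts as occupied if any replicate point falls in it, which makes
kernel smoothing unnecessary.  Cells are half-open squares
``[left, right) x [bottom, top)`` indexed by ``floor((coord - origin)/size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import TrackCloud

__all__ = ["GridSpec", "CellSet", "DensityGrid", "occupied_cells", "range_size",
           "density_surface", "cellsets_from_clouds"]


@dataclass(frozen=True)
class GridSpec:
    """Square equal-area grid: cell size in km and an origin (default (0, 0))."""

    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    def cell_indices(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Integer (i, j) cell index of each point; half-open convention."""
        i = np.floor((np.asarray(x, dtype=float) - self.origin[0]) / self.cell_size)
        j = np.floor((np.asarray(y, dtype=float) - self.origin[1]) / self.cell_size)
        return i.astype(np.int64), j.astype(np.int64)

    def cell_centers(self, cells) -> tuple[np.ndarray, np.ndarray]:
        cells = np.asarray(list(cells), dtype=float).reshape(-1, 2)
        cx = self.origin[0] + (cells[:, 0] + 0.5) * self.cell_size
        cy = self.origin[1] + (cells[:, 1] + 0.5) * self.cell_size
        return cx, cy


@dataclass(frozen=True)
class CellSet:
    """Set of occupied cell indices on a grid, owned by a bird or group."""

    grid: GridSpec
    cells: frozenset
    owner: str | None = None

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class DensityGrid:
    """Cell -> value map with a declared normalization.

    ``per_bird_fraction``: per bird, the fraction of that bird's replicate
    points in each cell, averaged across birds (sums to 1).
    ``bird_count``: number of birds whose cell set contains the cell.
    """

    grid: GridSpec
    values: dict = field(default_factory=dict)
    normalization: str = "per_bird_fraction"

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, j, v) for (i, j), v in sorted(self.values.items())]
        return pd.DataFrame(rows, columns=["cell_i", "cell_j", "value"])


def _month_mask(dates: pd.DatetimeIndex, months) -> np.ndarray:
    if months is None:
        return np.ones(len(dates), dtype=bool)
    months = {int(m) for m in months}
    return np.isin(dates.month, list(months))


def occupied_cells(cloud: TrackCloud, grid: GridSpec, months=None,
                   min_visits: int = 1) -> CellSet:
    """Union of cells touched by any replicate point of one bird-winter.

    ``months`` optionally restricts to calendar months (e.g. ``[10, 11]``).
    ``min_visits`` (default 1) raises the occupancy threshold to cells with
    at least that many replicate points.
    """
    mask = _month_mask(cloud.dates, months)
    if not mask.any():
        warnings.warn(f"month filter selects no dates for bird {cloud.bird_id}; "
                      "returning an empty cell set", stacklevel=2)
        return CellSet(grid=grid, cells=frozenset(), owner=cloud.bird_id)
    xs = cloud.x[:, mask].ravel()
    ys = cloud.y[:, mask].ravel()
    i, j = grid.cell_indices(xs, ys)
    if min_visits <= 1:
        cells = frozenset(zip(i.tolist(), j.tolist()))
    else:
        pairs, counts = np.unique(np.column_stack([i, j]), axis=0, return_counts=True)
        cells = frozenset(map(tuple, pairs[counts >= min_visits].tolist()))
    return CellSet(grid=grid, cells=cells, owner=cloud.bird_id)


def range_size(cellset: CellSet) -> int:
    """Individual range size: the number of occupied grid cells."""
    return len(cellset.cells)


def cellsets_from_clouds(clouds, grid: GridSpec, months=None) -> list[CellSet]:
    return [occupied_cells(c, grid, months=months) for c in clouds]


def density_surface(clouds, grid: GridSpec, normalization: str = "per_bird_fraction",
                    months=None) -> DensityGrid:
    """Across-bird density surface from all replicate points."""
    clouds = list(clouds)
    if not clouds:
        raise ValueError("density_surface requires at least one cloud")
    if normalization not in ("per_bird_fraction", "bird_count"):
        raise ValueError(f"unknown normalization {normalization!r}; expected "
                         "'per_bird_fraction' or 'bird_count'")
    values: dict = {}
    if normalization == "per_bird_fraction":
        for cloud in clouds:
            mask = _month_mask(cloud.dates, months)
            i, j = grid.cell_indices(cloud.x[:, mask].ravel(), cloud.y[:, mask].ravel())
            pairs, counts = np.unique(np.column_stack([i, j]), axis=0, return_counts=True)
            frac = counts / counts.sum()
            for (ci, cj), f in zip(pairs.tolist(), frac):
                values[(ci, cj)] = values.get((ci, cj), 0.0) + f / len(clouds)
    else:
        for cloud in clouds:
            for cell in occupied_cells(cloud, grid, months=months).cells:
                values[cell] = values.get(cell, 0) + 1
    return DensityGrid(grid=grid, values=values, normalization=normalization)
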
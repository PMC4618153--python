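"""Individual site fidelity across spatial scales.

Birds tracked in two consecutive winters are compared with themselves
(repeat pairs) via the grid-cell similarity index computed over *all*
replicate locations, month by month and pooled, at a series of grid
sizes (default 10–400 km).  The null contrast is the same index for
random pairs of *different* birds of the same sex and colony from
consecutive years.
"""

from __future__ import annotations

import warnings
from itertools import groupby

import numpy as np
import pandas as pd

from .gridding import GridSpec, occupied_cells
from .sharing import similarity_index

__all__ = ["DEFAULT_SCALES", "repeat_fidelity", "random_pair_null"]

DEFAULT_SCALES = (10.0, 25.0, 45.0, 50.0, 100.0, 200.0, 400.0)
DEFAULT_MONTHS = (10, 11, 12, 1, 2, "pooled")


def _pair_rows(pair_id: str, pair_type: str, cloud1, cloud2, scales, months) -> list[dict]:
    rows = []
    for scale in scales:
        grid = GridSpec(cell_size=float(scale))
        for month in months:
            sel = None if month == "pooled" else [int(month)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty month selections -> empty sets
                a = occupied_cells(cloud1, grid, months=sel)
                b = occupied_cells(cloud2, grid, months=sel)
            if len(a) == 0 and len(b) == 0:
                continue  # index undefined for two empty selections
            rows.append({
                "pair_id": pair_id,
                "pair_type": pair_type,
                "month": month,
                "scale_km": float(scale),
                "index": similarity_index(a, b),
            })
    return rows


def repeat_fidelity(clouds, scales=DEFAULT_SCALES, months=DEFAULT_MONTHS) -> pd.DataFrame:
    """Similarity of each returner bird's two consecutive winters.

    Birds contributing anything other than exactly two consecutive
    winters are skipped with a warning.  Returns a tidy frame with
    columns ``pair_id, pair_type, month, scale_km, index`` (pair_type
    'repeat'); the index is symmetric, so which winter is 'first' does
    not matter.
    """
    rows = []
    keyed = sorted(clouds, key=lambda c: (c.bird_id, c.year))
    for bird, grp in groupby(keyed, key=lambda c: c.bird_id):
        grp = list(grp)
        years = [c.year for c in grp]
        if len(grp) != 2 or years[1] - years[0] != 1:
            if len(grp) != 1:  # single-winter birds are the normal case, not a warning
                warnings.warn(f"bird {bird} has winters {years}; expected exactly two "
                              "consecutive winters — skipped", stacklevel=2)
            continue
        rows.extend(_pair_rows(bird, "repeat", grp[0], grp[1], scales, months))
    return pd.DataFrame(rows, columns=["pair_id", "pair_type", "month", "scale_km", "index"])


def random_pair_null(clouds, n_pairs: int = 59, scales=DEFAULT_SCALES,
                     months=DEFAULT_MONTHS, seed=None) -> pd.DataFrame:
    """Null fidelity from random same-sex, same-colony, consecutive-year pairs.

    Pairs are sampled uniformly without replacement from the universe of
    (bird A winter y, bird B winter y+1) combinations with matching sex
    and colony and A ≠ B.  Errors if the universe is smaller than
    ``n_pairs``.
    """
    clouds = list(clouds)
    universe = []
    for c1 in clouds:
        for c2 in clouds:
            if (c2.year == c1.year + 1 and c1.bird_id != c2.bird_id
                    and c1.sex == c2.sex and c1.colony == c2.colony):
                universe.append((c1, c2))
    if len(universe) < n_pairs:
        raise ValueError(f"constrained pair universe has only {len(universe)} pairs; "
                         f"{n_pairs} requested")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=n_pairs, replace=False)
    rows = []
    for k in sorted(chosen.tolist()):
        c1, c2 = universe[k]
        pair_id = f"{c1.bird_id}|{c1.year}+{c2.bird_id}|{c2.year}"
        rows.extend(_pair_rows(pair_id, "random", c1, c2, scales, months))
    return pd.DataFrame(rows, columns=["pair_id", "pair_type", "month", "scale_km", "index"])


def fidelity_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean index per (pair_type, month, scale) — the repeat-vs-random contrast."""
    return (results.groupby(["pair_type", "month", "scale_km"], sort=True)["index"]
            .agg(["mean", "std", "count"]).reset_index())
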
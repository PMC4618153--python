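"""Between-group space sharing: similarity index, permutation null, and
cumulative-area (saturation) curves.

The similarity index between two groups is the number of 45-km grid cells
occupied by both groups divided by the total cells used by either — a
Jaccard index on group-level cell unions, equal to 1 for identical groups.
Significance is assessed by randomly reassigning birds to groups (birds,
not points, are the exchangeable unit) while preserving group sizes, and
counting permuted indices smaller than the observed one.

Saturation curves record the expected cumulative number of distinct cells
occupied as birds are added in random order; shallower curves indicate
more shared space use within a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridding import CellSet, GridSpec

__all__ = ["GroupComparison", "SaturationCurve", "similarity_index",
           "permutation_test", "saturation_curve"]


@dataclass
class GroupComparison:
    """Observed similarity index plus its permutation distribution."""

    labels: tuple
    group_sizes: tuple
    observed_index: float
    permuted_indices: np.ndarray
    n_iterations: int
    p_value: float
    tie_rule: str

    def summary(self) -> dict:
        perm = np.asarray(self.permuted_indices, dtype=float)
        return {
            "labels": list(self.labels),
            "group_sizes": list(self.group_sizes),
            "observed_index": float(self.observed_index),
            "p_value": float(self.p_value),
            "n_iterations": int(self.n_iterations),
            "tie_rule": self.tie_rule,
            "permuted_mean": float(perm.mean()),
            "permuted_sd": float(perm.std(ddof=1)) if perm.size > 1 else 0.0,
        }


@dataclass
class SaturationCurve:
    """Mean cumulative occupied-cell count as birds are added in random order."""

    n_birds: np.ndarray
    mean_cumulative_cells: np.ndarray
    n_iterations: int
    curves: np.ndarray | None = None  # (n_iterations, n_birds) if retained


def _as_cells(obj) -> tuple[frozenset, GridSpec | None]:
    if isinstance(obj, CellSet):
        return obj.cells, obj.grid
    return frozenset(obj), None


def similarity_index(cells_a, cells_b) -> float:
    """Jaccard-type index |A ∩ B| / |A ∪ B| on group-level cell unions.

    Accepts :class:`~trackcloud.gridding.CellSet` objects (grids must
    match) or plain sets of cell indices.  Symmetric, bounded in [0, 1],
    and exactly 1 iff the two sets are equal.  Undefined (error) when both
    sets are empty.
    """
    a, grid_a = _as_cells(cells_a)
    b, grid_b = _as_cells(cells_b)
    if grid_a is not None and grid_b is not None and grid_a != grid_b:
        raise ValueError("similarity_index requires cell sets on the same grid")
    union = len(a | b)
    if union == 0:
        raise ValueError("similarity index is undefined for two empty cell sets")
    return len(a & b) / union


def _bool_matrix(cellsets: list[CellSet]) -> np.ndarray:
    """(n_birds, n_cells) boolean occupancy over the union cell universe."""
    universe = sorted(set().union(*(cs.cells for cs in cellsets)))
    index = {c: k for k, c in enumerate(universe)}
    mat = np.zeros((len(cellsets), len(universe)), dtype=bool)
    for r, cs in enumerate(cellsets):
        cols = [index[c] for c in cs.cells]
        mat[r, cols] = True
    return mat


def _jaccard_rows(mat: np.ndarray, in_a: np.ndarray) -> float:
    ua = mat[in_a].any(axis=0)
    ub = mat[~in_a].any(axis=0)
    union = (ua | ub).sum()
    return float((ua & ub).sum() / union) if union else np.nan


def permutation_test(cellsets: list[CellSet], labels, n_iterations: int = 10_000,
                     seed=None, tie_rule: str = "plus_one") -> GroupComparison:
    """Permutation test of the group similarity index.

    Birds are randomly reassigned to the two groups, preserving group
    sizes, ``n_iterations`` times.  The p-value is the probability of a
    permuted index *smaller* than the observed one (small p: the groups
    share less space than random assignment would produce):

    * ``tie_rule='strict'``  — ``#{perm < obs} / n``;
    * ``tie_rule='plus_one'`` (default) — ``(1 + #{perm <= obs}) / (n + 1)``,
      which cannot return 0 and is well behaved under ties (in the fully
      degenerate case of identical birds it returns 1, while the strict
      rule returns 0).
    """
    cellsets = list(cellsets)
    labels = np.asarray(labels)
    if len(labels) != len(cellsets):
        raise ValueError("labels must align with cellsets")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two group labels required, got {uniq}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if tie_rule not in ("strict", "plus_one"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    grids = {cs.grid for cs in cellsets}
    if len(grids) > 1:
        raise ValueError("all cell sets must share one grid")
    in_a = labels == uniq[0]
    n_a = int(in_a.sum())
    if n_a == 0 or n_a == len(labels):
        raise ValueError(f"each group needs at least one bird (sizes "
                         f"{n_a}/{len(labels) - n_a})")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = _bool_matrix(cellsets)
    observed = _jaccard_rows(mat, in_a)

    perm = np.empty(n_iterations)
    n = len(cellsets)
    for it in range(n_iterations):
        sel = np.zeros(n, dtype=bool)
        sel[rng.choice(n, size=n_a, replace=False)] = True
        perm[it] = _jaccard_rows(mat, sel)

    if tie_rule == "strict":
        p = float((perm < observed).sum() / n_iterations)
    else:
        p = float((1 + (perm <= observed).sum()) / (n_iterations + 1))
    return GroupComparison(labels=tuple(uniq), group_sizes=(n_a, n - n_a),
                           observed_index=observed, permuted_indices=perm,
                           n_iterations=n_iterations, p_value=p, tie_rule=tie_rule)


def saturation_curve(cellsets: list[CellSet], n_iterations: int = 10_000,
                     seed=None, keep_curves: bool = False) -> SaturationCurve:
    """Cumulative occupied-area curve over random bird orderings.

    Each iteration draws a uniformly random bird order without replacement
    and records the cumulative union size as each bird is added; the mean
    over iterations is returned.  The endpoint equals the full union size
    in every iteration.  When all ``n!`` orderings are fewer than the
    requested iterations, they are enumerated exactly once each, so the
    mean is the exact expectation.
    """
    from itertools import permutations
    from math import factorial

    cellsets = list(cellsets)
    if not cellsets:
        raise ValueError("saturation_curve requires at least one bird")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = _bool_matrix(cellsets)
    n = len(cellsets)
    n_exact = factorial(n) if n <= 8 else None
    if n_exact is not None and n_exact <= n_iterations:
        orders = list(permutations(range(n)))
    else:
        orders = [rng.permutation(n) for _ in range(n_iterations)]
    curves = np.empty((len(orders), n))
    for it, order in enumerate(orders):
        cum = np.logical_or.accumulate(mat[list(order)], axis=0)
        curves[it] = cum.sum(axis=1)
    n_iterations = len(orders)
    return SaturationCurve(
        n_birds=np.arange(1, n + 1),
        mean_cumulative_cells=curves.mean(axis=0),
        n_iterations=n_iterations,
        curves=curves if keep_curves else None,
    )
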
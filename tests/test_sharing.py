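from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trackcloud import (CellSet, GridSpec, permutation_test, saturation_curve,
                        similarity_index)

GRID = GridSpec(45.0)


def _cs(cells, owner="b"):
    return CellSet(grid=GRID, cells=frozenset(cells), owner=owner)


def test_identical_groups_give_exactly_one():
    cells = {(0, 0), (1, 2), (-3, 4)}
    assert similarity_index(_cs(cells), _cs(cells)) == 1.0


def test_disjoint_groups_give_zero():
    assert similarity_index(_cs({(0, 0)}), _cs({(5, 5)})) == 0.0


def test_partial_overlap_set_arithmetic():
    a = _cs({(0, 0), (0, 1), (0, 2)})
    b = _cs({(0, 1), (0, 2), (0, 3)})
    assert similarity_index(a, b) == 0.5
    assert similarity_index(b, a) == 0.5  # symmetric


def test_grid_mismatch_and_double_empty_rejected():
    other = CellSet(grid=GridSpec(5.0), cells=frozenset({(0, 0)}), owner="x")
    with pytest.raises(ValueError, match="grid"):
        similarity_index(_cs({(0, 0)}), other)
    with pytest.raises(ValueError, match="empty"):
        similarity_index(_cs(set()), _cs(set()))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(a=st.sets(st.tuples(st.integers(-4, 4), st.integers(-4, 4)), max_size=10),
       b=st.sets(st.tuples(st.integers(-4, 4), st.integers(-4, 4)), max_size=10))
def test_similarity_bounds_and_identity_property(a, b):
    if not a and not b:
        return
    s = similarity_index(_cs(a), _cs(b))
    assert 0.0 <= s <= 1.0
    assert (s == 1.0) == (a == b)
    assert s == similarity_index(_cs(b), _cs(a))


# --- permutation test -------------------------------------------------------

BIRDS = [
    _cs({(0, 0), (0, 1), (1, 1)}, "b1"),
    _cs({(0, 0), (2, 2)}, "b2"),
    _cs({(0, 1), (1, 1), (3, 3)}, "b3"),
    _cs({(2, 2), (3, 3), (4, 4)}, "b4"),
]
LABELS = ["g1", "g1", "g2", "g2"]


def exact_strict_p(cellsets, n_a):
    """Enumerate every split of the birds into groups of size n_a."""
    n = len(cellsets)
    obs_a = frozenset().union(*(cs.cells for cs in cellsets[:n_a]))
    obs_b = frozenset().union(*(cs.cells for cs in cellsets[n_a:]))
    obs = len(obs_a & obs_b) / len(obs_a | obs_b)
    smaller = total = 0
    for combo in combinations(range(n), n_a):
        ua = frozenset().union(*(cellsets[i].cells for i in combo))
        ub = frozenset().union(*(cellsets[i].cells for i in range(n) if i not in combo))
        idx = len(ua & ub) / len(ua | ub)
        smaller += idx < obs
        total += 1
    return obs, smaller / total


def test_monte_carlo_p_matches_exhaustive_enumeration():
    obs, p_exact = exact_strict_p(BIRDS, 2)
    gc = permutation_test(BIRDS, LABELS, n_iterations=10_000, seed=0,
                          tie_rule="strict")
    assert gc.observed_index == pytest.approx(obs)
    sd = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / 10_000)
    assert abs(gc.p_value - p_exact) <= 3 * sd + 1e-12


def test_degenerate_identical_birds_tie_rules():
    same = [_cs({(0, 0), (1, 1)}, f"b{i}") for i in range(4)]
    strict = permutation_test(same, LABELS, n_iterations=200, seed=1,
                              tie_rule="strict")
    plus = permutation_test(same, LABELS, n_iterations=200, seed=1,
                            tie_rule="plus_one")
    assert strict.observed_index == 1.0
    assert strict.p_value == 0.0
    assert plus.p_value == 1.0


def test_permutation_seed_reproducible_and_order_invariant():
    a = permutation_test(BIRDS, LABELS, n_iterations=500, seed=7)
    b = permutation_test(BIRDS, LABELS, n_iterations=500, seed=7)
    assert a.p_value == b.p_value
    np.testing.assert_array_equal(a.permuted_indices, b.permuted_indices)
    # observed index does not depend on bird ordering
    order = [2, 0, 3, 1]
    c = permutation_test([BIRDS[i] for i in order], [LABELS[i] for i in order],
                         n_iterations=500, seed=7)
    assert c.observed_index == a.observed_index


def test_permutation_input_validation():
    with pytest.raises(ValueError, match="two group labels"):
        permutation_test(BIRDS, ["g1"] * 4, n_iterations=10, seed=0)
    with pytest.raises(ValueError, match="labels must align"):
        permutation_test(BIRDS, ["g1", "g2"], n_iterations=10, seed=0)


# --- saturation curve -------------------------------------------------------

def test_single_bird_curve_is_its_range_size():
    sc = saturation_curve([BIRDS[0]], n_iterations=10, seed=0)
    assert sc.mean_cumulative_cells.tolist() == [len(BIRDS[0].cells)]


def test_three_bird_mean_curve_equals_exact_ordering_average():
    birds = BIRDS[:3]
    exact = np.zeros(3)
    for order in permutations(range(3)):
        seen = set()
        for k, i in enumerate(order):
            seen |= birds[i].cells
            exact[k] += len(seen)
    exact /= 6
    # 6 orderings < requested iterations -> exhaustive enumeration, exact mean
    sc = saturation_curve(birds, n_iterations=4000, seed=2, keep_curves=True)
    union = len(frozenset().union(*(b.cells for b in birds)))
    assert np.all(sc.curves[:, -1] == union)  # endpoint in every iteration
    np.testing.assert_allclose(sc.mean_cumulative_cells, exact, rtol=1e-12)


def test_mean_curve_is_monotone_non_decreasing():
    sc = saturation_curve(BIRDS, n_iterations=200, seed=3)
    assert np.all(np.diff(sc.mean_cumulative_cells) >= 0)
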
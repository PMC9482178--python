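"""Entropy, mutual information and the adjusted-MI adjacency."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mifilter import (
    CountTable,
    DiscretizationScheme,
    adjusted_mi_matrix,
    discretize,
    entropy,
    joint_entropy,
    mi_matrix,
    mutual_information,
)

from conftest import random_count_table


# ---------------------------------------------------------------------------
# brute-force oracles: plain dictionary counting, no shared code with mi.py
# ---------------------------------------------------------------------------


def oracle_entropy(x) -> float:
    n = len(x)
    return -sum((c / n) * math.log(c / n) for c in Counter(x).values())


def oracle_joint_entropy(x, y) -> float:
    return oracle_entropy(list(zip(x, y)))


def oracle_mi(x, y) -> float:
    n = len(x)
    px, py = Counter(x), Counter(y)
    pxy = Counter(zip(x, y))
    total = 0.0
    for (a, b), c in pxy.items():
        total += (c / n) * math.log((c / n) / ((px[a] / n) * (py[b] / n)))
    return total


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def test_constant_vector_collapses_to_one_bin():
    for method in ("equal_width", "equal_frequency"):
        lab = discretize(np.array([5.0, 5, 5, 5]), DiscretizationScheme(method, 4))
        assert set(lab) == {0}


def test_equal_width_symmetric_split():
    lab = discretize(np.array([0.0, 0, 10, 10]), DiscretizationScheme("equal_width", 2))
    assert lab.tolist() == [0, 0, 1, 1]
    p = np.bincount(lab) / lab.size
    assert p.tolist() == [0.5, 0.5]


def test_equal_width_occupancy_matches_histogram_tally():
    rng = np.random.default_rng(42)
    x = rng.integers(0, 10, 100).astype(float)
    lab = discretize(x, DiscretizationScheme("equal_width", 10))
    expected, _ = np.histogram(x, bins=10, range=(x.min(), x.max()))
    assert np.bincount(lab, minlength=10).tolist() == expected.tolist()


def test_every_value_maps_to_exactly_one_bin():
    rng = np.random.default_rng(7)
    x = rng.exponential(5.0, 200)
    for method in ("equal_width", "equal_frequency"):
        for nb in (1, 3, "sturges", "sqrt_n"):
            lab = discretize(x, DiscretizationScheme(method, nb))
            assert lab.shape == x.shape
            assert lab.min() >= 0
            p = np.bincount(lab) / lab.size
            assert p.sum() == pytest.approx(1.0)


def test_equal_frequency_balances_occupancy():
    x = np.arange(100, dtype=float)
    lab = discretize(x, DiscretizationScheme("equal_frequency", 4))
    assert np.bincount(lab).tolist() == [25, 25, 25, 25]


def test_discretize_rejects_degenerate_input():
    with pytest.raises(ValueError):
        discretize(np.array([1.0]))
    with pytest.raises(ValueError):
        DiscretizationScheme("equal_width", 0)
    with pytest.raises(ValueError):
        DiscretizationScheme("kmeans")


# ---------------------------------------------------------------------------
# scalar information quantities
# ---------------------------------------------------------------------------


def test_entropy_reference_values():
    assert entropy(np.zeros(10, dtype=int)) == 0.0
    assert entropy(np.array([0, 1, 0, 1])) == pytest.approx(math.log(2))
    # p = (0.5, 0.25, 0.25) against direct summation
    x = np.array([0, 0, 1, 2])
    assert entropy(x) == pytest.approx(oracle_entropy(x.tolist()), abs=1e-12)


def test_entropy_rejects_empty_input():
    with pytest.raises(ValueError):
        entropy(np.array([], dtype=int))


def test_joint_entropy_reference_values():
    x = np.array([0, 1, 0, 1, 2, 2])
    assert joint_entropy(x, x) == pytest.approx(entropy(x))
    # independent uniform pair: all 4 combinations equally frequent
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 0, 1])
    assert joint_entropy(a, b) == pytest.approx(math.log(4))
    with pytest.raises(ValueError):
        joint_entropy(a, b[:-1])


def test_mutual_information_reference_values():
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 0, 1])
    assert mutual_information(a, b) == 0.0
    x = np.array([0, 1, 2, 0, 1, 2])
    assert mutual_information(x, x) == pytest.approx(entropy(x))


@given(st.data())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_information_identities_on_random_pairs(data):
    """Symmetry, bounds and oracle agreement for arbitrary binned pairs."""
    n = data.draw(st.integers(3, 40))
    x = np.array(data.draw(st.lists(st.integers(0, 4), min_size=n, max_size=n)))
    y = np.array(data.draw(st.lists(st.integers(0, 4), min_size=n, max_size=n)))
    hx, hy, hxy = entropy(x), entropy(y), joint_entropy(x, y)
    mi = mutual_information(x, y)
    assert hxy == pytest.approx(joint_entropy(y, x), abs=1e-12)
    assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
    assert max(hx, hy) <= hxy + 1e-12
    assert hxy <= hx + hy + 1e-12
    assert -1e-12 <= mi <= hxy + 1e-12
    assert mi == pytest.approx(oracle_mi(x.tolist(), y.tolist()), abs=1e-10)


# ---------------------------------------------------------------------------
# matrix estimators
# ---------------------------------------------------------------------------


def test_identical_columns_have_unit_adjusted_mi():
    vals = np.tile(np.array([[3], [1], [4], [1], [5]]), (1, 2))
    table = CountTable(vals, tuple("abcde"), ("x", "y"))
    adj = adjusted_mi_matrix(table)
    assert adj.values[0, 1] == pytest.approx(1.0)


def test_independent_columns_have_near_zero_adjusted_mi():
    rng = np.random.default_rng(11)
    vals = rng.integers(0, 50, size=(1000, 2))
    table = CountTable(vals, tuple(f"s{i}" for i in range(1000)), ("x", "y"))
    adj = adjusted_mi_matrix(table)
    assert adj.values[0, 1] <= 0.05


def test_matrix_agrees_with_scalar_path_and_oracle():
    """The vectorised all-pairs estimator equals the per-pair definition."""
    rng = np.random.default_rng(3)
    scheme = DiscretizationScheme("equal_width", 4)
    for _ in range(20):
        table = random_count_table(rng)
        raw = mi_matrix(table, scheme)
        from mifilter.mi import label_matrix

        labels = label_matrix(table, scheme)
        m = table.n_taxa
        for j in range(m):
            assert raw.entropies[j] == pytest.approx(
                oracle_entropy(labels[:, j].tolist()), abs=1e-10
            )
            for jp in range(j + 1, m):
                x, y = labels[:, j].tolist(), labels[:, jp].tolist()
                assert raw.joint_entropies[j, jp] == pytest.approx(
                    oracle_joint_entropy(x, y), abs=1e-10
                )
                assert raw.mi[j, jp] == pytest.approx(oracle_mi(x, y), abs=1e-10)


def test_adjacency_contract(mock_adj):
    """0 ≤ values ≤ 1, symmetry and exact unit diagonal."""
    v = mock_adj.values
    assert v.min() >= 0.0 and v.max() <= 1.0
    np.testing.assert_array_equal(v, v.T)
    np.testing.assert_array_equal(np.diag(v), np.ones(v.shape[0]))


def test_adjusted_mi_is_log_base_invariant():
    rng = np.random.default_rng(5)
    table = random_count_table(rng)
    scheme = DiscretizationScheme("equal_width", 4)
    adj = adjusted_mi_matrix(table, scheme)
    from mifilter.mi import label_matrix

    labels = label_matrix(table, scheme)
    for j in range(table.n_taxa):
        for jp in range(j + 1, table.n_taxa):
            x, y = labels[:, j], labels[:, jp]
            hxy_bits = joint_entropy(x, y, base=2)
            mi_bits = mutual_information(x, y, base=2)
            expected = mi_bits / hxy_bits if hxy_bits > 0 else 0.0
            assert adj.values[j, jp] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_taxon_shares_no_information():
    vals = np.column_stack(
        [np.full(20, 7), np.arange(20), np.arange(20) % 3]
    )
    table = CountTable(vals, tuple(f"s{i}" for i in range(20)), ("const", "a", "b"))
    adj = adjusted_mi_matrix(table)
    assert adj.values[0, 1] == 0.0 and adj.values[0, 2] == 0.0
    assert adj.values[0, 0] == 1.0


def test_sample_permutation_leaves_matrix_unchanged(tiny_table):
    adj = adjusted_mi_matrix(tiny_table)
    rng = np.random.default_rng(0)
    perm = rng.permutation(tiny_table.n_samples)
    shuffled = tiny_table.select_samples(perm)
    np.testing.assert_allclose(adjusted_mi_matrix(shuffled).values, adj.values)


def test_taxon_permutation_permutes_rows_and_columns(tiny_table):
    adj = adjusted_mi_matrix(tiny_table)
    order = [2, 0, 1]
    reordered = tiny_table.select_taxa(order)
    expected = adj.values[np.ix_(order, order)]
    np.testing.assert_allclose(adjusted_mi_matrix(reordered).values, expected)
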
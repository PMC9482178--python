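"""Hard thresholding, scale-free fitting and threshold selection."""

import numpy as np
import pytest

from mifilter import (
    AdjustedMIMatrix,
    degree_distribution,
    fit_power_law,
    hard_threshold,
    isolated_taxa,
    scan_thresholds,
)

from conftest import symmetric_unit_matrix


def adj_from(values) -> AdjustedMIMatrix:
    values = np.asarray(values, dtype=float)
    ids = tuple(f"t{j}" for j in range(values.shape[0]))
    return AdjustedMIMatrix(values, ids)


def three_taxon_adj():
    v = np.array(
        [
            [1.0, 0.3, 0.5],
            [0.3, 1.0, 0.45],
            [0.5, 0.45, 1.0],
        ]
    )
    return adj_from(v)


def test_zero_threshold_connects_everything():
    adj = three_taxon_adj()
    net = hard_threshold(adj, 0.0)
    assert net.degrees.tolist() == [2, 2, 2]


def test_threshold_boundary_is_inclusive():
    net = hard_threshold(three_taxon_adj(), 0.45)
    # edges kept: 0.5 and 0.45; the 0.3 edge is gone
    assert net.values[0, 2] == 1 and net.values[1, 2] == 1 and net.values[0, 1] == 0
    assert net.degrees.tolist() == [1, 1, 2]


def test_threshold_outside_unit_interval_rejected():
    for tau in (-0.1, 1.2):
        with pytest.raises(ValueError):
            hard_threshold(three_taxon_adj(), tau)


def test_edge_monotonicity_in_tau():
    rng = np.random.default_rng(0)
    adj = adj_from(symmetric_unit_matrix(rng, 12))
    taus = np.sort(rng.random(6))
    nets = [hard_threshold(adj, t) for t in taus]
    for lo, hi in zip(nets, nets[1:]):
        assert np.all(hi.values <= lo.values)
        assert np.all(hi.degrees <= lo.degrees)
        assert hi.mean_connectivity <= lo.mean_connectivity


def test_degrees_never_count_the_diagonal():
    adj = adj_from(np.eye(5))
    net = hard_threshold(adj, 0.5)
    assert net.degrees.tolist() == [0] * 5


def test_degree_distribution_complete_and_star():
    complete = adj_from(np.ones((4, 4)))
    k, p = degree_distribution(hard_threshold(complete, 0.5))
    assert k.tolist() == [3] and p.tolist() == [1.0]

    star = np.eye(5)
    star[0, 1:] = star[1:, 0] = 0.9
    k, p = degree_distribution(hard_threshold(adj_from(star), 0.5))
    assert dict(zip(k.tolist(), p.tolist())) == {1: 0.8, 4: 0.2}


def test_degree_distribution_matches_brute_force_tally():
    rng = np.random.default_rng(1)
    adj = adj_from(symmetric_unit_matrix(rng, 15))
    net = hard_threshold(adj, 0.6)
    k, p = degree_distribution(net)
    counts = {}
    for d in net.degrees:
        counts[d] = counts.get(d, 0) + 1
    assert dict(zip(k.tolist(), p.tolist())) == {
        d: c / 15 for d, c in counts.items()
    }
    assert p.sum() == pytest.approx(1.0)


def test_exact_power_law_recovers_exponent():
    k = np.array([1, 2, 4, 8], dtype=float)
    p = k ** -2.0
    p = p / p.sum()
    fit = fit_power_law(k, p)
    assert fit.gamma_hat == pytest.approx(2.0)
    assert fit.slope == pytest.approx(-2.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.defined and not fit.low_support


def test_two_point_fit_is_perfect_but_flagged():
    fit = fit_power_law(np.array([1, 3]), np.array([0.7, 0.3]))
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.low_support


def test_undefined_fit_below_two_points():
    fit = fit_power_law(np.array([0, 2]), np.array([0.9, 0.1]))
    assert not fit.defined
    assert np.isnan(fit.r_squared)


def test_noisy_power_law_matches_independent_ols():
    rng = np.random.default_rng(123)
    k = np.arange(1, 12, dtype=float)
    logp = -1.8 * np.log(k) + 0.3 + rng.normal(0, 0.1, k.size)
    p = np.exp(logp)
    fit = fit_power_law(k, p)
    # independent least-squares oracle
    x = np.column_stack([np.log(k), np.ones(k.size)])
    beta, res, *_ = np.linalg.lstsq(x, np.log(p), rcond=None)
    assert fit.slope == pytest.approx(beta[0], abs=1e-10)
    assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
    assert abs(fit.gamma_hat - 1.8) < 0.3
    ss_tot = np.sum((np.log(p) - np.log(p).mean()) ** 2)
    assert fit.r_squared == pytest.approx(1 - res[0] / ss_tot, abs=1e-10)


def test_singleton_grid_selects_its_only_value():
    rng = np.random.default_rng(2)
    adj = adj_from(symmetric_unit_matrix(rng, 10))
    scan = scan_thresholds(adj, np.array([0.4]))
    assert scan.selected_tau == 0.4


def test_equal_r_squared_ties_break_by_mean_connectivity():
    # two disjoint copies of a graph whose degree distribution is an exact
    # power law over k in {1, 2, 4}; one copy at weight 0.9, one at 0.5.
    # At tau = 0.5 both copies contribute, at 0.9 only one: P(k) is
    # proportionally identical (R^2 = 1 on 3 points in both cases) but mean
    # connectivity halves, so the tie must resolve to tau = 0.5.
    def component_edges(offset):
        h, l1, l2, l3, l4, p1, p2 = range(offset, offset + 7)
        return [(h, l1), (h, l2), (h, l3), (h, l4), (l1, l2), (p1, p2)]

    v = np.eye(14)
    for a, b in component_edges(0):
        v[a, b] = v[b, a] = 0.9
    for a, b in component_edges(7):
        v[a, b] = v[b, a] = 0.5
    adj = adj_from(v)
    scan = scan_thresholds(adj, np.array([0.5, 0.9]))
    t = scan.table.set_index("tau")
    assert t.loc[0.5, "r_squared"] == pytest.approx(1.0)
    assert t.loc[0.9, "r_squared"] == pytest.approx(1.0)
    assert t.loc[0.5, "n_fit_points"] == 3 and t.loc[0.9, "n_fit_points"] == 3
    assert t.loc[0.5, "mean_connectivity"] > t.loc[0.9, "mean_connectivity"]
    assert scan.selected_tau == 0.5


def test_scan_errors_when_no_fit_is_defined():
    adj = adj_from(np.eye(6))  # no edges at any positive tau
    with pytest.raises(ValueError, match="undefined"):
        scan_thresholds(adj, np.array([0.5, 0.9]))


def test_isolated_taxa_partition_complete_graph():
    adj = adj_from(np.ones((4, 4)))
    kept, removed = isolated_taxa(hard_threshold(adj, 0.5))
    assert removed == [] and len(kept) == 4


def test_everything_removed_warns():
    adj = adj_from(np.eye(3) + 0.2 - 0.2 * np.eye(3))
    net = hard_threshold(adj, 0.9)
    with pytest.warns(UserWarning, match="isolated"):
        kept, removed = isolated_taxa(net)
    assert kept == [] and len(removed) == 3


def test_partition_is_exhaustive_and_disjoint(mock_adj):
    scan = scan_thresholds(mock_adj)
    net = hard_threshold(mock_adj, scan.selected_tau)
    kept, removed = isolated_taxa(net)
    assert sorted(kept + removed) == sorted(mock_adj.taxon_ids)
    assert not set(kept) & set(removed)


def test_mock_community_recovery_single_seed(mock_community, mock_adj):
    """On the strong-signal preset, all true taxa survive the selected τ."""
    _, labels = mock_community
    scan = scan_thresholds(mock_adj)
    kept, removed = isolated_taxa(hard_threshold(mock_adj, scan.selected_tau))
    true_ids = set(labels[labels == "true"].index)
    assert true_ids <= set(kept)
    contaminants = set(labels[labels == "contaminant"].index)
    assert len(contaminants & set(removed)) >= 0.8 * len(contaminants)
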
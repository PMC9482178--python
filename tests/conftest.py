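import numpy as np
import pandas as pd
import pytest

from mifilter import (
    CountTable,
    adjusted_mi_matrix,
    brooks_like_spec,
    generate_community,
)


@pytest.fixture(scope="session")
def mock_community():
    """One strong-signal mock community with ground-truth labels."""
    table, labels = generate_community(brooks_like_spec(seed=1))
    return table, labels


@pytest.fixture(scope="session")
def mock_adj(mock_community):
    table, _ = mock_community
    return adjusted_mi_matrix(table)


@pytest.fixture()
def tiny_table():
    """4 samples × 3 taxa, entries chosen by hand."""
    values = np.array(
        [
            [10, 0, 3],
            [0, 5, 3],
            [7, 2, 0],
            [1, 9, 3],
        ]
    )
    return CountTable(values, ("s1", "s2", "s3", "s4"), ("A", "B", "C"))


def random_count_table(rng: np.random.Generator, max_n=50, max_m=6) -> CountTable:
    n = int(rng.integers(4, max_n + 1))
    m = int(rng.integers(2, max_m + 1))
    values = rng.integers(0, 10, size=(n, m))
    return CountTable(
        values,
        tuple(f"s{i}" for i in range(n)),
        tuple(f"t{j}" for j in range(m)),
    )


def symmetric_unit_matrix(rng: np.random.Generator, m: int) -> np.ndarray:
    """Random symmetric matrix in [0,1] with unit diagonal."""
    a = rng.random((m, m))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


@pytest.fixture()
def labels_series():
    def make(taxon_ids, n_true):
        return pd.Series(
            ["true"] * n_true + ["contaminant"] * (len(taxon_ids) - n_true),
            index=list(taxon_ids),
        )

    return make
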
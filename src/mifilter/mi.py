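"""Discretization, entropy and mutual-information estimation.

Taxon abundance vectors are binned with simple histogram partitions, and all
information quantities are plug-in estimates computed from the empirical bin
probabilities.  Pairwise shared information is normalised by the pair's joint
entropy, giving the *adjusted* mutual information

    I~(X_j; X_j') = I(X_j; X_j') / H(X_j, X_j'),

a symmetric adjacency weight in [0, 1] with unit diagonal, which is the edge
weight of the taxon co-occurrence network used throughout this package.
Because the normalisation is a ratio of two entropies, the adjusted value is
invariant to the logarithm base; internally everything is computed in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .table import CountTable

__all__ = [
    "DiscretizationScheme",
    "MIMatrix",
    "AdjustedMIMatrix",
    "discretize",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "mi_matrix",
    "adjusted_mi_matrix",
]

# Plug-in MI can dip below zero only through float round-off; anything more
# negative than this indicates an internal inconsistency.
_NEG_TOL = 1e-12


@dataclass(frozen=True)
class DiscretizationScheme:
    """Histogram partition used to bin each taxon's abundances.

    ``n_bins`` may be a fixed positive integer or one of the rule tags
    ``"sturges"`` (ceil(log2 n) + 1, the default) and ``"sqrt_n"``.
    ``equal_width`` splits the observed range into bins of equal width;
    ``equal_frequency`` places bin edges at empirical quantiles (duplicate
    edges collapse, so heavily tied vectors yield fewer occupied bins).
    A constant vector always collapses to a single bin.
    """

    method: Literal["equal_width", "equal_frequency"] = "equal_width"
    n_bins: int | str = "sturges"

    def __post_init__(self) -> None:
        if self.method not in ("equal_width", "equal_frequency"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if isinstance(self.n_bins, str):
            if self.n_bins not in ("sturges", "sqrt_n"):
                raise ValueError(f"unknown bin rule {self.n_bins!r}")
        elif int(self.n_bins) < 1:
            raise ValueError("n_bins must be >= 1")

    def resolve_bins(self, n_obs: int) -> int:
        if self.n_bins == "sturges":
            return int(math.ceil(math.log2(max(n_obs, 2)))) + 1
        if self.n_bins == "sqrt_n":
            return int(math.ceil(math.sqrt(n_obs)))
        return int(self.n_bins)


def discretize(x: np.ndarray, scheme: DiscretizationScheme | None = None) -> np.ndarray:
    """Bin one abundance vector; returns integer bin labels in [0, n_bins).

    Every observed value maps to exactly one bin.  A constant vector (with
    either scheme) collapses to a single occupied bin rather than failing.
    """
    scheme = scheme or DiscretizationScheme()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with at least 2 observations")
    nb = scheme.resolve_bins(x.size)
    lo, hi = x.min(), x.max()
    if lo == hi or nb == 1:
        return np.zeros(x.size, dtype=np.int64)
    if scheme.method == "equal_width":
        lab = np.floor((x - lo) / (hi - lo) * nb).astype(np.int64)
        return np.minimum(lab, nb - 1)
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, nb + 1)))
    # interior edges only; right-closed upper bin so the maximum maps inside
    return np.searchsorted(edges[1:-1], x, side="right").astype(np.int64)


def _as_labels(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError(f"{name} is empty: invalid taxon column")
    if not np.issubdtype(x.dtype, np.integer):
        raise TypeError(f"{name} must be an integer bin-label vector")
    return x.ravel()


def entropy(x: np.ndarray, base: float = math.e) -> float:
    """Plug-in entropy of a binned vector, in nats by default."""
    x = _as_labels(x)
    counts = np.bincount(x)
    p = counts[counts > 0] / x.size
    h = float(-(p * np.log(p)).sum())
    return max(h, 0.0) / math.log(base)


def joint_entropy(x: np.ndarray, y: np.ndarray, base: float = math.e) -> float:
    """Plug-in joint entropy H(X, Y) of two binned vectors."""
    x, y = _as_labels(x), _as_labels(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    ny = int(y.max()) + 1
    return entropy(x * ny + y, base=base)


def mutual_information(x: np.ndarray, y: np.ndarray, base: float = math.e) -> float:
    """I(X;Y) = H(X) + H(Y) − H(X,Y), clamped to be non-negative.

    Round-off negatives larger than ``1e-12`` (in nats) raise, since the
    plug-in estimate is analytically non-negative.
    """
    hx = entropy(x, base=base)
    hy = entropy(y, base=base)
    hxy = joint_entropy(x, y, base=base)
    mi = hx + hy - hxy
    if mi < 0.0:
        if mi * math.log(base) < -_NEG_TOL:
            raise ArithmeticError(f"mutual information {mi} below round-off tolerance")
        mi = 0.0
    return mi


# ---------------------------------------------------------------------------
# matrix estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIMatrix:
    """Raw information quantities for all taxon pairs (nats)."""

    entropies: np.ndarray            # (m,) H_j
    joint_entropies: np.ndarray      # (m, m) symmetric, diag = H_j
    mi: np.ndarray                   # (m, m) symmetric, diag = H_j
    taxon_ids: tuple[str, ...]


@dataclass(frozen=True)
class AdjustedMIMatrix:
    """Joint-entropy–normalised MI adjacency: values in [0,1], unit diagonal."""

    values: np.ndarray
    taxon_ids: tuple[str, ...]
    scheme: DiscretizationScheme = field(default_factory=DiscretizationScheme)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    def submatrix(self, index: np.ndarray) -> "AdjustedMIMatrix":
        """Principal submatrix on the given taxon positions."""
        idx = np.asarray(index, dtype=np.intp)
        return AdjustedMIMatrix(
            self.values[np.ix_(idx, idx)],
            tuple(self.taxon_ids[j] for j in idx),
            self.scheme,
        )

    def to_dataframe(self):
        import pandas as pd

        ids = list(self.taxon_ids)
        return pd.DataFrame(self.values.copy(), index=ids, columns=ids)


def label_matrix(
    table: CountTable, scheme: DiscretizationScheme | None = None
) -> np.ndarray:
    """Discretize every taxon column; (n, m) integer labels."""
    scheme = scheme or DiscretizationScheme()
    return np.column_stack(
        [discretize(table.values[:, j], scheme) for j in range(table.n_taxa)]
    )


def _pairwise_entropies(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All marginal and pairwise joint entropies from a label matrix.

    Joint histograms for all pairs come from one sparse indicator product
    (O.T @ O where O one-hot encodes every column), then per-pair c·log c
    block sums — O(n·m²) instead of a Python loop over pairs.
    """
    n, m = labels.shape
    levels = labels.max(axis=0) + 1
    starts = np.concatenate([[0], np.cumsum(levels)])[:-1]
    codes = (labels + starts[None, :]).ravel()
    rows = np.repeat(np.arange(n), m)
    k_tot = int(levels.sum())
    onehot = sp.csr_matrix(
        (np.ones(n * m), (rows, codes)), shape=(n, k_tot), dtype=np.float64
    )
    joint_counts = (onehot.T @ onehot).toarray()
    with np.errstate(divide="ignore", invalid="ignore"):
        clogc = np.where(joint_counts > 0, joint_counts * np.log(joint_counts), 0.0)
    bounds = starts  # reduceat over block boundaries
    block = np.add.reduceat(np.add.reduceat(clogc, bounds, axis=0), bounds, axis=1)
    h_joint = np.log(n) - block / n
    h_joint = (h_joint + h_joint.T) / 2.0
    h_joint = np.maximum(h_joint, 0.0)
    h_marg = np.diag(h_joint).copy()
    return h_marg, h_joint


def mi_matrix(
    table: CountTable, scheme: DiscretizationScheme | None = None
) -> MIMatrix:
    """Marginal/joint entropies and raw MI for every taxon pair."""
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    scheme = scheme or DiscretizationScheme()
    labels = label_matrix(table, scheme)
    h, h_joint = _pairwise_entropies(labels)
    mi = h[:, None] + h[None, :] - h_joint
    if mi.min() < -_NEG_TOL:
        raise ArithmeticError("negative mutual information beyond round-off tolerance")
    np.clip(mi, 0.0, None, out=mi)
    np.fill_diagonal(mi, h)
    return MIMatrix(h, h_joint, mi, table.taxon_ids)


def adjusted_mi_matrix(
    table: CountTable, scheme: DiscretizationScheme | None = None
) -> AdjustedMIMatrix:
    """Adjacency of adjusted (joint-entropy–normalised) mutual information.

    Degenerate pairs where both taxa are constant (joint entropy 0) get
    weight 0; a zero-variance taxon therefore shares no information with
    anything.  The diagonal is exactly 1.
    """
    scheme = scheme or DiscretizationScheme()
    raw = mi_matrix(table, scheme)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(raw.joint_entropies > 0, raw.mi / raw.joint_entropies, 0.0)
    np.clip(adj, 0.0, 1.0, out=adj)
    np.fill_diagonal(adj, 1.0)
    return AdjustedMIMatrix(adj, table.taxon_ids, scheme)


def adjusted_mi_from_labels(labels: np.ndarray) -> np.ndarray:
    """Adjusted-MI matrix straight from a pre-binned label matrix.

    Used by resampling code that re-evaluates the network many times on
    permuted labels without re-discretizing.
    """
    h, h_joint = _pairwise_entropies(labels)
    mi = np.clip(h[:, None] + h[None, :] - h_joint, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(h_joint > 0, mi / h_joint, 0.0)
    np.clip(adj, 0.0, 1.0, out=adj)
    np.fill_diagonal(adj, 1.0)
    return adj
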
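"""Weighted connectivity degrees and Frobenius information loss.

Each taxon's weighted degree d_j is the sum of its adjusted-MI edge weights
(diagonal excluded).  Removing the taxa whose degree falls below successive
sample quantiles of d yields a nested family of principal submatrices; the
information lost at step k is

    Λ_k = 1 − ‖I~'_k‖²_F / ‖I~‖²_F,

the fraction of squared Frobenius mass of the full adjacency given up by the
removal.  Λ is 0 when nothing is removed, 1 when everything is, and is
non-decreasing as the retained set shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mi import AdjustedMIMatrix

__all__ = [
    "WeightedDegrees",
    "LossProfile",
    "weighted_degrees",
    "remove_below_quantile",
    "information_loss",
    "loss_profile",
    "sequential_loss",
    "default_quantile_grid",
]


def default_quantile_grid() -> np.ndarray:
    """Canonical removal grid: 0.01 to 0.96 in steps of 0.05."""
    return np.round(0.01 + 0.05 * np.arange(20), 2)


@dataclass(frozen=True)
class WeightedDegrees:
    """Off-diagonal row sums of the adjusted-MI matrix, with a removal order."""

    d: np.ndarray                  # (m,)
    order: np.ndarray              # taxon positions sorted by (d, taxon id)
    taxon_ids: tuple[str, ...]


@dataclass(frozen=True)
class LossProfile:
    quantiles: np.ndarray          # q_k grid
    removed_counts: np.ndarray     # r_k
    losses: np.ndarray             # Λ_k
    deltas: np.ndarray             # Δ_{k+1} = Λ_{k+1} − Λ_k (first entry vs 0)
    retained_sets: tuple[np.ndarray, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantile": self.quantiles,
                "n_removed": self.removed_counts,
                "lambda": self.losses,
                "delta": self.deltas,
            }
        )


def weighted_degrees(adj: AdjustedMIMatrix) -> WeightedDegrees:
    """Weighted degree of every taxon; ties ordered by taxon id."""
    if adj.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    d = adj.values.sum(axis=1) - np.diag(adj.values)
    order = np.lexsort((np.asarray(adj.taxon_ids), d))
    return WeightedDegrees(d, order, adj.taxon_ids)


def _loss_from_retained(values: np.ndarray, retained: np.ndarray) -> float:
    total = float((values ** 2).sum())
    if retained.size == 0:
        return 1.0
    kept = float((values[np.ix_(retained, retained)] ** 2).sum())
    return 1.0 - kept / total


def _removed_mask(d: np.ndarray, q: float) -> np.ndarray:
    """Taxa strictly below the (type-7) empirical q-quantile of d.

    Degrees are rounded at 1e-12 first so that taxa whose weighted degrees
    are equal up to summation round-off are treated as exact ties (all-equal
    degrees must remove nothing at any quantile).
    """
    if not 0.0 <= q < 1.0:
        raise ValueError(f"quantile must lie in [0, 1), got {q}")
    dr = np.round(d, 12)
    return dr < np.quantile(dr, q)


def remove_below_quantile(
    adj: AdjustedMIMatrix, wd: WeightedDegrees, q: float
) -> tuple[AdjustedMIMatrix, np.ndarray]:
    """Drop taxa with weighted degree below the q-quantile.

    Returns the principal submatrix on the retained taxa and the removed
    positions.  Pairwise MI is unchanged by dropping other columns, so the
    submatrix is exact — no re-estimation is needed.
    """
    removed = np.flatnonzero(_removed_mask(wd.d, q))
    retained = np.flatnonzero(~_removed_mask(wd.d, q))
    return adj.submatrix(retained), removed


def information_loss(full: AdjustedMIMatrix, reduced: AdjustedMIMatrix) -> float:
    """Λ = 1 − ‖reduced‖²_F / ‖full‖²_F for a principal submatrix."""
    lookup = {t: j for j, t in enumerate(full.taxon_ids)}
    try:
        retained = np.array([lookup[t] for t in reduced.taxon_ids], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"reduced matrix contains taxon {exc.args[0]!r} absent from the full matrix"
        ) from None
    return _loss_from_retained(full.values, retained)


def loss_profile(
    adj: AdjustedMIMatrix, grid: np.ndarray | None = None
) -> LossProfile:
    """Λ_k, Δ_{k+1} and retained sets along a quantile grid."""
    grid = default_quantile_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or (np.diff(grid) <= 0).any():
        raise ValueError("quantile grid must be non-empty and strictly increasing")
    if grid[0] < 0 or grid[-1] >= 1:
        raise ValueError("quantile grid must lie within [0, 1)")
    wd = weighted_degrees(adj)
    losses, counts, retained_sets = [], [], []
    for q in grid:
        removed = _removed_mask(wd.d, float(q))
        retained = np.flatnonzero(~removed)
        counts.append(int(removed.sum()))
        retained_sets.append(retained)
        losses.append(_loss_from_retained(adj.values, retained))
    losses_arr = np.asarray(losses)
    deltas = np.diff(losses_arr, prepend=0.0)
    return LossProfile(
        grid, np.asarray(counts), losses_arr, deltas, tuple(retained_sets)
    )


def sequential_loss(adj: AdjustedMIMatrix) -> pd.DataFrame:
    """One-at-a-time removal trajectory in increasing-degree order.

    Returns a row per removal step with the taxon removed and the cumulative
    information loss after that removal.
    """
    wd = weighted_degrees(adj)
    m = adj.n_taxa
    rows = []
    remaining = list(wd.order)
    for step, pos in enumerate(wd.order, start=1):
        remaining.remove(pos)
        lam = _loss_from_retained(adj.values, np.asarray(remaining, dtype=np.intp))
        rows.append(
            {
                "n_removed": step,
                "taxon_id": adj.taxon_ids[pos],
                "weighted_degree": wd.d[pos],
                "lambda": lam,
            }
        )
    assert len(rows) == m
    return pd.DataFrame(rows)
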
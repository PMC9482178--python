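"""Hard thresholding, scale-free fit and threshold selection.

The weighted adjusted-MI adjacency is binarised with an inclusive signum
rule (edge iff weight ≥ τ).  A candidate τ is scored by how well the
resulting degree distribution follows a power law P(k) ~ k^(−γ): ordinary
least squares of log P(k) on log k, scored by the coefficient of
determination R².  The selected τ maximises R², with mean connectivity k̄
breaking ties.  Taxa isolated (degree 0) at the selected τ are the putative
contaminants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mi import AdjustedMIMatrix

__all__ = [
    "UnweightedAdjacency",
    "ScaleFreeFit",
    "ThresholdScan",
    "hard_threshold",
    "degree_distribution",
    "fit_power_law",
    "scan_thresholds",
    "isolated_taxa",
    "default_tau_grid",
]


def default_tau_grid() -> np.ndarray:
    """Canonical scan grid: 0.05 to 0.95 in steps of 0.05."""
    return np.round(np.arange(1, 20) * 0.05, 2)


@dataclass(frozen=True)
class UnweightedAdjacency:
    """Binary taxon network at threshold tau.

    ``degrees`` counts off-diagonal connections only; the stored diagonal is
    1 by the adjacency convention but never contributes to degrees.
    """

    values: np.ndarray          # (m, m) uint8, symmetric, diag 1
    tau: float
    degrees: np.ndarray         # (m,) ints, off-diagonal only
    taxon_ids: tuple[str, ...]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def mean_connectivity(self) -> float:
        return float(self.degrees.mean())

    def edge_list(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n_taxa, k=1)
        mask = self.values[iu] == 1
        return [
            (self.taxon_ids[a], self.taxon_ids[b])
            for a, b in zip(iu[0][mask], iu[1][mask])
        ]


@dataclass(frozen=True)
class ScaleFreeFit:
    """Log-log OLS fit of the empirical degree distribution.

    ``slope`` is the raw regression slope of log P(k) on log k (a power law
    gives a negative slope); ``gamma_hat`` is its magnitude.  Fits with only
    two usable support points are perfect by construction and flagged via
    ``low_support``; fits with fewer are ``defined = False``.
    """

    slope: float
    gamma_hat: float
    intercept: float
    r_squared: float
    mean_connectivity: float
    degrees: np.ndarray          # distinct k in the distribution
    probabilities: np.ndarray    # P(k), sums to 1
    n_points: int                # support points entering the fit (k >= 1)
    defined: bool
    low_support: bool


@dataclass(frozen=True)
class ThresholdScan:
    """Per-τ network characteristics and the selected threshold."""

    table: pd.DataFrame          # tau, r_squared, mean_connectivity, gamma_hat, ...
    selected_tau: float
    fits: dict[float, ScaleFreeFit]


def hard_threshold(adj: AdjustedMIMatrix, tau: float) -> UnweightedAdjacency:
    """Signum-threshold the weighted adjacency: edge iff weight ≥ τ (inclusive)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold tau must lie in [0, 1], got {tau}")
    vals = (adj.values >= tau).astype(np.uint8)
    np.fill_diagonal(vals, 1)
    degrees = vals.sum(axis=1).astype(np.int64) - 1  # diagonal excluded
    return UnweightedAdjacency(vals, float(tau), degrees, adj.taxon_ids)


def degree_distribution(net: UnweightedAdjacency) -> tuple[np.ndarray, np.ndarray]:
    """Distinct observed degrees k and their node fractions P(k)."""
    if net.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    k, counts = np.unique(net.degrees, return_counts=True)
    return k, counts / net.n_taxa


def fit_power_law(
    degrees: np.ndarray,
    probabilities: np.ndarray,
    mean_connectivity: float = float("nan"),
) -> ScaleFreeFit:
    """OLS of log P(k) on log k over the k ≥ 1 support.

    Isolated-node mass (k = 0) cannot enter a log-log fit and is excluded
    here, but still counts toward the mean connectivity.
    """
    k = np.asarray(degrees, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    mask = k >= 1
    k, p = k[mask], p[mask]
    n_pts = k.size
    if n_pts < 2:
        return ScaleFreeFit(
            np.nan, np.nan, np.nan, np.nan, mean_connectivity,
            np.asarray(degrees), np.asarray(probabilities),
            n_pts, defined=False, low_support=True,
        )
    x, y = np.log(k), np.log(p)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_res <= 1e-14:
        r2 = 1.0
    elif ss_tot <= 1e-14:
        r2 = 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return ScaleFreeFit(
        float(slope), abs(float(slope)), float(intercept), r2, mean_connectivity,
        np.asarray(degrees), np.asarray(probabilities),
        n_pts, defined=True, low_support=n_pts == 2,
    )


def scan_thresholds(
    adj: AdjustedMIMatrix, grid: np.ndarray | None = None
) -> ThresholdScan:
    """Fit the scale-free criterion on every τ in the grid and pick the best.

    Selection: maximal R² among defined fits, ties broken by larger mean
    connectivity.  Two-point fits are perfect by construction and carry no
    evidence of scale-freeness, so they are excluded from selection whenever
    any better-supported fit exists (they remain in the reported table,
    flagged ``low_support``).  Raises if no τ yields a defined fit (fewer
    than two distinct positive degrees everywhere).
    """
    grid = default_tau_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("threshold grid values must lie in [0, 1]")

    rows, fits = [], {}
    for tau in grid:
        net = hard_threshold(adj, float(tau))
        k, p = degree_distribution(net)
        fit = fit_power_law(k, p, mean_connectivity=net.mean_connectivity)
        fits[float(tau)] = fit
        rows.append(
            {
                "tau": float(tau),
                "r_squared": fit.r_squared,
                "mean_connectivity": net.mean_connectivity,
                "gamma_hat": fit.gamma_hat,
                "slope": fit.slope,
                "n_fit_points": fit.n_points,
                "defined": fit.defined,
                "low_support": fit.low_support,
            }
        )
    scan = pd.DataFrame(rows)
    defined = scan[scan["defined"]]
    if defined.empty:
        raise ValueError(
            "scale-free fit undefined at every threshold; "
            "try a denser tau grid or a different discretization"
        )
    usable = defined[~defined["low_support"]]
    if usable.empty:
        usable = defined
    best = usable.sort_values(
        ["r_squared", "mean_connectivity"], kind="mergesort"
    ).iloc[-1]
    return ThresholdScan(scan, float(best["tau"]), fits)


def isolated_taxa(net: UnweightedAdjacency) -> tuple[list[str], list[str]]:
    """Partition taxa into (kept, removed): removed = degree-0 nodes.

    Isolated taxa share no (thresholded) information with the rest of the
    community and are treated as putative contaminants.
    """
    removed = [t for t, d in zip(net.taxon_ids, net.degrees) if d == 0]
    kept = [t for t, d in zip(net.taxon_ids, net.degrees) if d > 0]
    if not kept:
        warnings.warn(
            f"every taxon is isolated at tau={net.tau}; nothing would be kept",
            stacklevel=2,
        )
    return kept, removed
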
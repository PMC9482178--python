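"""End-to-end MI filtering: adjacency → threshold selection → isolated-node removal.

The default pipeline mirrors the method's primary rule: estimate the
adjusted-MI network, select the hard threshold by the scale-free criterion,
and discard the taxa left isolated at that threshold.  Quantile-based
removal guided by the step tests is available as an opt-in second stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import FilterReport, labels_to_binary
from .inference import StepScan, scan_steps
from .loss import weighted_degrees
from .mi import AdjustedMIMatrix, DiscretizationScheme, adjusted_mi_matrix
from .network import ThresholdScan, UnweightedAdjacency, hard_threshold, isolated_taxa, scan_thresholds
from .table import CountTable

__all__ = ["PipelineResult", "run_mi_filter", "mi_filter_report"]


@dataclass(frozen=True)
class PipelineResult:
    adj: AdjustedMIMatrix
    scan: ThresholdScan
    network: UnweightedAdjacency
    kept: tuple[str, ...]
    removed: tuple[str, ...]
    filtered_table: CountTable
    step_scan: StepScan | None = None

    @property
    def selected_tau(self) -> float:
        return self.scan.selected_tau

    def report(self, labels: pd.Series | dict | None = None) -> FilterReport:
        pct = None
        if labels is not None:
            d = labels_to_binary(labels, self.adj.taxon_ids)
            n_contam = int((d == 0).sum())
            if n_contam:
                kept_set = set(self.kept)
                kept_contam = sum(
                    1
                    for t, lab in zip(self.adj.taxon_ids, d)
                    if lab == 0 and t in kept_set
                )
                pct = 100.0 * kept_contam / n_contam
        return FilterReport("MI-based", self.kept, len(self.adj.taxon_ids), pct)


def run_mi_filter(
    table: CountTable,
    *,
    scheme: DiscretizationScheme | None = None,
    tau_grid: np.ndarray | None = None,
    tau: float | None = None,
    quantile_removal: bool = False,
    quantile_grid: np.ndarray | None = None,
    n_permutations: int = 500,
    n_bootstrap: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    decision_test: str = "permutation",
) -> PipelineResult:
    """Run the MI filter and return every intermediate artifact.

    ``tau`` pins the hard threshold; otherwise it is selected by scanning
    ``tau_grid`` for the best scale-free fit.  With ``quantile_removal`` the
    step tests additionally trim retained taxa up to the recommended
    quantile level.
    """
    scheme = scheme or DiscretizationScheme()
    adj = adjusted_mi_matrix(table, scheme)
    scan = scan_thresholds(adj, tau_grid)
    chosen = scan.selected_tau if tau is None else float(tau)
    net = hard_threshold(adj, chosen)
    kept, removed = isolated_taxa(net)

    step_scan = None
    if quantile_removal:
        step_scan = scan_steps(
            table,
            scheme=scheme,
            adj=adj,
            grid=quantile_grid,
            n_permutations=n_permutations,
            n_bootstrap=n_bootstrap,
            alpha=alpha,
            seed=seed,
            decision_test=decision_test,
        )
        from .loss import _removed_mask

        wd = weighted_degrees(adj)
        mask = _removed_mask(wd.d, step_scan.recommended_quantile)
        kept_set = set(kept)
        quantile_removed = {
            t for t, flag in zip(adj.taxon_ids, mask) if flag
        }
        removed = [t for t in adj.taxon_ids if t not in kept_set or t in quantile_removed]
        kept = [t for t in adj.taxon_ids if t not in removed]

    filtered = table.select_taxa(kept) if kept else table.select_taxa(np.array([], int))
    return PipelineResult(
        adj, scan, net, tuple(kept), tuple(removed), filtered, step_scan
    )


def mi_filter_report(
    table: CountTable,
    labels: pd.Series | dict | None = None,
    **kwargs,
) -> FilterReport:
    """Convenience wrapper returning just the comparison-table row."""
    return run_mi_filter(table, **kwargs).report(labels)
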
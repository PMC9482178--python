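"""Traditional abundance/prevalence filters, ROC evaluation and comparison.

Four ad hoc filters commonly used on amplicon tables are implemented for
benchmarking against the MI-network filter:

1. keep taxa whose per-sample relative abundance exceeds a threshold
   (strictly) in at least one sample;
2. keep taxa with at least ``min_reads`` reads in at least ``min_samples``
   samples (both inclusive);
3. keep taxa present (nonzero) in strictly more than ``min_prevalence``
   samples;
4. first drop samples with fewer than 100 reads, then keep taxa with at
   least 10 total reads that are present in at least 1% of the remaining
   samples.

With ground-truth labels available (mock communities, simulations) each
filter is summarised by the number of taxa preserved, the percentage
filtered and the percentage of contamination preserved, and the MI network
is scored by an ROC curve over the hard threshold τ: at each τ a taxon is
predicted "true" iff it is non-isolated (degree ≥ 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mi import AdjustedMIMatrix
from .table import CountTable

__all__ = [
    "FilterReport",
    "ROCResult",
    "traditional1",
    "traditional2",
    "traditional3",
    "traditional4",
    "roc_analysis",
    "comparison_report",
    "labels_to_binary",
]

TRUE_LABEL = "true"
CONTAMINANT_LABEL = "contaminant"


@dataclass(frozen=True)
class FilterReport:
    method: str
    retained_taxa: tuple[str, ...]
    n_total: int
    percent_contamination_preserved: float | None = None

    @property
    def n_preserved(self) -> int:
        return len(self.retained_taxa)

    @property
    def percent_filtered(self) -> float:
        return 100.0 * (self.n_total - self.n_preserved) / self.n_total


@dataclass(frozen=True)
class ROCResult:
    points: pd.DataFrame          # tau, tpf, fpf
    auc: float


def labels_to_binary(labels: pd.Series | dict, taxon_ids) -> np.ndarray:
    """Map {true, contaminant} labels onto taxon order as a 0/1 vector."""
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    missing = [t for t in taxon_ids if t not in labels.index]
    if missing:
        raise KeyError(f"labels missing for taxa: {missing[:5]}")
    vals = labels.reindex(list(taxon_ids))
    bad = sorted(set(vals.unique()) - {TRUE_LABEL, CONTAMINANT_LABEL})
    if bad:
        raise ValueError(f"unknown labels {bad}; expected 'true'/'contaminant'")
    return (vals == TRUE_LABEL).to_numpy().astype(int)


def _report(
    method: str,
    table: CountTable,
    keep_mask: np.ndarray,
    labels: pd.Series | dict | None,
) -> FilterReport:
    retained = tuple(t for t, k in zip(table.taxon_ids, keep_mask) if k)
    pct_contam = None
    if labels is not None:
        d = labels_to_binary(labels, table.taxon_ids)
        n_contam = int((d == 0).sum())
        if n_contam:
            kept_contam = int(((d == 0) & keep_mask).sum())
            pct_contam = 100.0 * kept_contam / n_contam
    return FilterReport(method, retained, table.n_taxa, pct_contam)


def traditional1(
    table: CountTable,
    rel_abund_threshold: float,
    labels: pd.Series | dict | None = None,
) -> FilterReport:
    """Keep taxa exceeding a relative-abundance threshold in ≥ 1 sample (strict >)."""
    if not 0.0 < rel_abund_threshold < 1.0:
        raise ValueError("relative-abundance threshold must lie in (0, 1)")
    totals = table.sample_totals().astype(float)
    nonempty = totals > 0
    if not nonempty.all():
        warnings.warn(
            f"{int((~nonempty).sum())} all-zero sample(s) excluded from "
            "relative-abundance computation",
            stacklevel=2,
        )
    rel = table.values[nonempty] / totals[nonempty, None]
    keep = (rel > rel_abund_threshold).any(axis=0)
    return _report(
        f"Traditional 1-{100 * rel_abund_threshold:g}%", table, keep, labels
    )


def traditional2(
    table: CountTable,
    min_reads: int = 5,
    min_samples: int = 3,
    labels: pd.Series | dict | None = None,
) -> FilterReport:
    """Keep taxa with ≥ min_reads reads in ≥ min_samples samples (inclusive)."""
    keep = (table.values >= min_reads).sum(axis=0) >= min_samples
    return _report("Traditional 2", table, keep, labels)


def traditional3(
    table: CountTable,
    min_prevalence: int = 5,
    labels: pd.Series | dict | None = None,
) -> FilterReport:
    """Keep taxa present in strictly more than min_prevalence samples."""
    keep = (table.values > 0).sum(axis=0) > min_prevalence
    return _report("Traditional 3", table, keep, labels)


def traditional4(
    table: CountTable,
    min_sample_reads: int = 100,
    min_taxon_reads: int = 10,
    min_prevalence_frac: float = 0.01,
    labels: pd.Series | dict | None = None,
) -> FilterReport:
    """Drop shallow samples first, then rare and low-prevalence taxa.

    Samples with fewer than ``min_sample_reads`` total reads are removed
    before both taxon rules are evaluated on the reduced table.
    """
    deep = np.flatnonzero(table.sample_totals() >= min_sample_reads)
    if deep.size == 0:
        raise ValueError("every sample falls below the read-depth cutoff")
    reduced = table.select_samples(deep)
    enough_reads = reduced.values.sum(axis=0) >= min_taxon_reads
    prevalence = (reduced.values > 0).sum(axis=0)
    prevalent = prevalence >= min_prevalence_frac * reduced.n_samples
    return _report("Traditional 4", table, enough_reads & prevalent, labels)


def roc_analysis(
    adj: AdjustedMIMatrix,
    labels: pd.Series | dict,
    grid: np.ndarray | None = None,
) -> ROCResult:
    """ROC of the non-isolation rule over the hard-threshold grid.

    At each τ a taxon is predicted to be a true community member iff it has
    degree ≥ 1 in the thresholded network.  Sweeping τ from 0 to above the
    largest edge weight traces the curve from (1, 1) to (0, 0); AUC is the
    trapezoid area.  Equivalent to ranking taxa by their strongest adjusted-
    MI edge.
    """
    d = labels_to_binary(labels, adj.taxon_ids)
    if d.min() == d.max():
        raise ValueError("labels contain a single class; AUC is undefined")
    if grid is None:
        off = adj.values[~np.eye(adj.n_taxa, dtype=bool)]
        grid = np.unique(np.concatenate([[0.0], off, [1.0]]))
    grid = np.asarray(grid, dtype=float)
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("tau grid must lie in [0, 1]")

    # strongest off-diagonal edge per taxon: non-isolated at tau iff score >= tau
    vals = adj.values.copy()
    np.fill_diagonal(vals, -np.inf)
    score = vals.max(axis=1)

    tpf = [(score[d == 1] >= t).mean() for t in grid]
    fpf = [(score[d == 0] >= t).mean() for t in grid]
    points = pd.DataFrame({"tau": grid, "tpf": tpf, "fpf": fpf})
    xs = np.concatenate([[0.0], np.sort(fpf), [1.0]])
    ys = np.concatenate([[0.0], np.sort(tpf), [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return ROCResult(points, auc)


def comparison_report(
    table: CountTable,
    labels: pd.Series | dict | None = None,
    reports: list[FilterReport] | None = None,
    include_mi: bool = True,
    **mi_kwargs,
) -> pd.DataFrame:
    """Tabulate filter performance, one row per method.

    Without labels the contamination column is omitted.  ``reports`` can
    supply pre-computed rows; otherwise the four traditional filters (with
    the 0.1%/1%/5% variants of the first) and, when ``include_mi``, the full
    MI pipeline are run.
    """
    if reports is None:
        reports = [
            traditional1(table, 0.001, labels),
            traditional1(table, 0.01, labels),
            traditional1(table, 0.05, labels),
            traditional2(table, labels=labels),
            traditional3(table, labels=labels),
            traditional4(table, labels=labels),
        ]
        if include_mi:
            from .pipeline import mi_filter_report

            reports.append(mi_filter_report(table, labels=labels, **mi_kwargs))
    rows = []
    for rep in reports:
        row = {
            "method": rep.method,
            "n_taxa_preserved": rep.n_preserved,
            "percent_filtered": round(rep.percent_filtered, 1),
        }
        if labels is not None:
            row["percent_contamination_preserved"] = (
                None
                if rep.percent_contamination_preserved is None
                else round(rep.percent_contamination_preserved, 1)
            )
        rows.append(row)
    return pd.DataFrame(rows)
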
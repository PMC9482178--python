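"""Reading and writing count tables, labels, matrices and networks.

All tabular artifacts are UTF-8, tab-separated with a header line; writers
prepend ``#``-prefixed comment lines carrying the serialized run
configuration so every output is self-describing, and readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .mi import AdjustedMIMatrix
from .network import UnweightedAdjacency
from .table import CountTable

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_labels",
    "write_labels",
    "write_labeled_matrix",
    "write_edge_list",
    "write_graphml",
    "write_frame",
    "write_metadata",
]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported count-table format {fmt!r} (tsv or csv)")
    return "," if fmt == "csv" else "\t"


def read_count_table(
    path: str | Path,
    fmt: str | None = None,
    taxa_as_rows: bool = False,
) -> CountTable:
    """Read a delimited count table (header = taxon ids, first column = sample ids).

    With ``taxa_as_rows`` the file holds taxa as rows and is transposed so
    downstream code always sees samples × taxa.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if taxa_as_rows:
        df = df.T
    arr = df.to_numpy()
    if arr.dtype == object:
        bad = np.argwhere(~np.vectorize(np.isreal)(arr))
        where = f"row {bad[0][0] + 2}, column {bad[0][1] + 2}" if bad.size else "?"
        raise ValueError(f"non-numeric entry in {path} at {where}")
    return CountTable.from_dataframe(df)


def _header_lines(config: RunConfig | None) -> str:
    if config is None:
        return ""
    return f"# mifilter config: {config.to_json()}\n"


def write_count_table(
    table: CountTable,
    path: str | Path,
    fmt: str | None = None,
    config: RunConfig | None = None,
) -> None:
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        table.to_dataframe().to_csv(fh, sep=sep, index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (taxon_id, label in {true, contaminant})."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs columns (taxon_id, label)")
    ser = df.set_index(df.columns[0])[df.columns[1]].str.strip().str.lower()
    bad = sorted(set(ser.unique()) - {"true", "contaminant"})
    if bad:
        raise ValueError(f"unknown labels in {path}: {bad}")
    ser.name = "label"
    return ser


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="taxon_id")


def write_labeled_matrix(
    adj: AdjustedMIMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        adj.to_dataframe().to_csv(fh, sep="\t", index_label="taxon_id")


def write_edge_list(
    obj: AdjustedMIMatrix | UnweightedAdjacency,
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    """TSV (source, target, weight); weight is 1 for unweighted networks."""
    ids = obj.taxon_ids
    vals = obj.values
    iu = np.triu_indices(len(ids), k=1)
    rows = [
        (ids[a], ids[b], float(vals[a, b]))
        for a, b in zip(*iu)
        if vals[a, b] > 0
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def _to_graph(obj: AdjustedMIMatrix | UnweightedAdjacency) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(obj.taxon_ids)
    ids, vals = obj.taxon_ids, obj.values
    iu = np.triu_indices(len(ids), k=1)
    for a, b in zip(*iu):
        if vals[a, b] > 0:
            g.add_edge(ids[a], ids[b], weight=float(vals[a, b]))
    return g


def write_graphml(
    obj: AdjustedMIMatrix | UnweightedAdjacency, path: str | Path
) -> None:
    nx.write_graphml(_to_graph(obj), str(path))


def write_frame(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def write_metadata(path: str | Path, config: RunConfig, **extra) -> None:
    """JSON sidecar with the full run configuration and package version."""
    from . import __version__

    payload = {"mifilter_version": __version__, "config": config.to_dict(), **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
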
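"""Count-table container for samples × taxa abundance matrices.

A 16S (or any amplicon/metagenomic) count table records, for each sample
``i`` and taxon ``j`` (ASV, OTU, species, ...), the number of sequence reads
``x_ij`` attributed to that taxon.  Rows are samples, columns are taxa; all
network operations in this package see this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountTable"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class CountTable:
    """Non-negative integer abundance matrix with sample and taxon labels.

    Parameters
    ----------
    values
        ``(n_samples, n_taxa)`` array of non-negative integers.
    sample_ids, taxon_ids
        Unique row / column labels, stored as tuples.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError(f"count matrix must be 2-D, got shape {vals.shape}")
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.allclose(vals, rounded, atol=0, rtol=0):
                bad = np.argwhere(vals != rounded)[0]
                raise ValueError(
                    f"non-integer count at sample row {bad[0]}, taxon column {bad[1]}"
                )
            vals = rounded.astype(np.int64)
        else:
            vals = vals.astype(np.int64)
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at sample row {bad[0]}, taxon column {bad[1]}"
            )
        sample_ids = tuple(str(s) for s in self.sample_ids)
        taxon_ids = tuple(str(t) for t in self.taxon_ids)
        if vals.shape != (len(sample_ids), len(taxon_ids)):
            raise ValueError(
                f"shape mismatch: values {vals.shape}, "
                f"{len(sample_ids)} sample ids, {len(taxon_ids)} taxon ids"
            )
        _check_unique(sample_ids, "sample")
        _check_unique(taxon_ids, "taxon")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)
        self.values.setflags(write=False)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        """Build from a samples × taxa DataFrame (index = sample ids)."""
        return cls(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    # -- subsetting --------------------------------------------------------
    def taxon_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {t: j for j, t in enumerate(self.taxon_ids)}
        try:
            return np.array([lookup[t] for t in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown taxon id {exc.args[0]!r}") from None

    def select_taxa(self, index: Iterable[int] | Iterable[str]) -> "CountTable":
        """Column subset; accepts integer positions or taxon ids."""
        idx = list(index)
        if idx and isinstance(idx[0], str):
            pos = self.taxon_indices(idx)  # type: ignore[arg-type]
        else:
            pos = np.asarray(idx, dtype=np.intp)
        return CountTable(
            self.values[:, pos],
            self.sample_ids,
            tuple(self.taxon_ids[j] for j in pos),
        )

    def select_samples(self, index: Iterable[int]) -> "CountTable":
        pos = np.asarray(list(index), dtype=np.intp)
        return CountTable(
            self.values[pos, :],
            tuple(self.sample_ids[i] for i in pos),
            self.taxon_ids,
        )

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample (library sizes)."""
        return self.values.sum(axis=1)
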
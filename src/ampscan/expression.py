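"""Genes × samples expression container with counts/RPKM unit tracking."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ExpressionMatrix:
    """Gene-level expression values with gene lengths and condition labels.

    Parameters
    ----------
    values
        DataFrame, genes (index) × samples (columns). Counts must be
        non-negative integers; RPKM non-negative reals.
    gene_lengths
        Series of gene-model lengths in bp, indexed like ``values``.
    conditions
        One condition label per sample column (e.g. ``otosphere``/``imop``).
    units
        ``"counts"`` or ``"rpkm"``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        gene_lengths: pd.Series | Mapping[str, int],
        conditions: Sequence[str],
        units: str = "counts",
    ):
        self.values = values.copy()
        self.gene_lengths = pd.Series(gene_lengths).reindex(values.index)
        self.conditions = list(conditions)
        if units not in ("counts", "rpkm"):
            raise ValueError(f"units must be 'counts' or 'rpkm', got {units!r}")
        self.units = units
        if len(self.conditions) != values.shape[1]:
            raise ValueError("need one condition label per sample column")
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise KeyError(f"gene lengths missing for {missing[:5]}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        arr = values.to_numpy()
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if units == "counts" and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.samples, self.conditions) if c == condition]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[ids], self.gene_lengths.loc[ids], self.conditions, self.units
        )

    def concat(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        """Column-wise concatenation of two matrices over the same genes."""
        if self.units != other.units:
            raise ValueError("cannot concatenate matrices with different units")
        if list(self.values.index) != list(other.values.index):
            raise ValueError("gene sets differ")
        return ExpressionMatrix(
            pd.concat([self.values, other.values], axis=1),
            self.gene_lengths,
            self.conditions + other.conditions,
            self.units,
        )

    # ------------------------------------------------------------------ I/O
    # TSV layout: header row = gene_id, length, then sample names; condition
    # labels are encoded as "<condition>.<replicate>" sample names.

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "length", self.gene_lengths)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        conditions: Sequence[str] | None = None,
        units: str = "counts",
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        if conditions is None:
            conditions = [c.rsplit(".", 1)[0] for c in df.columns]
        return cls(df, lengths, conditions, units)
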
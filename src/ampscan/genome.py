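"""Genome annotation and ChIP read-interval containers.

Coordinates are 0-based, half-open (BED convention) throughout the package.
The TSS of a ``+`` strand gene is its ``start``; for a ``-`` strand gene it
is ``end - 1`` (the last base of the half-open interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

FACTORS = ("POLII", "C-MYC", "SOX2")


@dataclass(frozen=True)
class GeneRecord:
    """One gene model: half-open genomic interval plus strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        """Strand-aware transcriptional start site (0-based position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """A set of gene records with the chromosome sizes they live on.

    Validates on construction: unique gene ids, strand in ``{+,-}``,
    ``0 <= start < end <= chrom length``, and known chromosomes.
    """

    def __init__(self, records: Iterable[GeneRecord], chrom_sizes: Mapping[str, int]):
        self.records: list[GeneRecord] = list(records)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            if rec.strand not in ("+", "-"):
                raise ValueError(f"{rec.gene_id}: strand must be '+' or '-', got {rec.strand!r}")
            if rec.chrom not in self.chrom_sizes:
                raise KeyError(f"{rec.gene_id}: unknown chromosome {rec.chrom!r}")
            size = self.chrom_sizes[rec.chrom]
            if not (0 <= rec.start < rec.end <= size):
                raise ValueError(
                    f"{rec.gene_id}: interval [{rec.start}, {rec.end}) outside [0, {size})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def gene_lengths(self) -> pd.Series:
        return pd.Series({r.gene_id: r.length for r in self.records}, name="length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "start": [r.start for r in self.records],
                "end": [r.end for r in self.records],
                "gene_id": [r.gene_id for r in self.records],
                "strand": [r.strand for r in self.records],
            }
        )

    # ------------------------------------------------------------------ I/O

    def write_bed(self, path: str | Path) -> None:
        """Write as BED6 (name in col 4, score 0, strand in col 6)."""
        df = self.to_frame()
        df.insert(4, "score", 0)
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path: str | Path, chrom_sizes: Mapping[str, int]) -> "GenomeAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str, "gene_id": str, "strand": str},
        )
        records = [
            GeneRecord(row.gene_id, row.chrom, int(row.start), int(row.end), row.strand)
            for row in df.itertuples()
        ]
        return cls(records, chrom_sizes)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{int(size)}\n")


class ReadSet:
    """Aligned read intervals for one ChIP factor.

    Stored as parallel arrays (chrom labels, starts, ends); ``total_reads``
    equals the number of intervals by construction.
    """

    def __init__(self, factor: str, chroms: Iterable[str], starts, ends):
        self.factor = factor
        self.chroms = np.asarray(list(chroms), dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if np.any(self.starts >= self.ends):
            raise ValueError("read intervals must satisfy start < end")

    @property
    def total_reads(self) -> int:
        return len(self.starts)

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted read midpoints per chromosome (for binary-search counting)."""
        mids = self.midpoints()
        out: dict[str, np.ndarray] = {}
        for chrom in np.unique(self.chroms):
            sel = mids[self.chroms == chrom]
            sel.sort()
            out[str(chrom)] = sel
        return out

    def write_bed(self, path: str | Path) -> None:
        """Write as BED3, sorted by (chrom, start)."""
        df = pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})
        df = df.sort_values(["chrom", "start"], kind="stable")
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path: str | Path, factor: str) -> "ReadSet":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end"], dtype={"chrom": str}
        )
        return cls(factor, df["chrom"], df["start"].to_numpy(), df["end"].to_numpy())
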
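"""Promoter-window occupancy calling and co-occupancy statistics.

A gene's promoter is the ±``flank`` window around its strand-aware TSS
(default ±5 kb). A factor is called *bound* at a promoter when the window
read count is enriched over a uniform-genome Poisson background at a
Benjamini–Hochberg FDR below ``q_threshold`` AND the fold enrichment over
the background expectation is at least ``min_enrichment``. Target genes of
a factor are genes bound by both RNA POLII and that factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAnnotation, ReadSet


@dataclass(frozen=True)
class PromoterWindow:
    """±flank window around a TSS, clamped to the chromosome."""

    gene_id: str
    chrom: str
    win_start: int
    win_end: int
    tss: int
    flank: int

    @property
    def nominal_length(self) -> int:
        """Unclamped window length; used for the background expectation so
        edge genes are not artificially enriched."""
        return 2 * self.flank


def build_tss_windows(annotation: GenomeAnnotation, flank: int = 5000) -> list[PromoterWindow]:
    """One promoter window per gene: ``[tss - flank, tss + flank)`` clamped
    to ``[0, chrom length)``."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows = []
    for rec in annotation:
        size = annotation.chrom_sizes[rec.chrom]
        tss = rec.tss
        windows.append(
            PromoterWindow(
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                win_start=max(0, tss - flank),
                win_end=min(size, tss + flank),
                tss=tss,
                flank=flank,
            )
        )
    return windows


def count_window_reads(
    windows: Sequence[PromoterWindow], readset: ReadSet, assignment: str = "midpoint"
) -> np.ndarray:
    """Per-window read counts.

    A read is assigned to a window iff its midpoint falls in
    ``[win_start, win_end)``; a read may count toward several overlapping
    windows. Binary search over per-chromosome sorted midpoints.
    """
    if assignment != "midpoint":
        raise ValueError(f"unknown assignment rule {assignment!r}")
    mids = readset.by_chrom()
    counts = np.zeros(len(windows), dtype=np.int64)
    for i, win in enumerate(windows):
        pos = mids.get(win.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, win.win_end, side="left") - np.searchsorted(
            pos, win.win_start, side="left"
        )
    return counts


def call_binding(
    counts: np.ndarray,
    readset: ReadSet,
    windows: Sequence[PromoterWindow],
    genome_size: int,
    q_threshold: float = 0.05,
    min_enrichment: float = 2.0,
) -> pd.DataFrame:
    """Poisson enrichment test per promoter window for one factor.

    Background expectation λ_g = total_reads × nominal_window_length / genome_size
    (uniform-genome model); p_g = P(Poisson(λ_g) ≥ count_g); q by
    Benjamini–Hochberg across genes; bound ⇔ q < q_threshold and
    count/λ ≥ min_enrichment.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if readset.total_reads <= 0:
        raise ValueError("readset has no reads")
    counts = np.asarray(counts, dtype=np.int64)
    if len(counts) != len(windows):
        raise ValueError("counts and windows length mismatch")
    lengths = np.array([w.nominal_length for w in windows], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("zero-length window")
    lam = readset.total_reads * lengths / float(genome_size)
    # upper tail P(X >= count) = sf(count - 1)
    p = stats.poisson.sf(counts - 1, lam)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    enrichment = counts / lam
    bound = (q < q_threshold) & (enrichment >= min_enrichment)
    return pd.DataFrame(
        {
            "gene_id": [w.gene_id for w in windows],
            "factor": readset.factor,
            "count": counts,
            "lambda": lam,
            "enrichment": enrichment,
            "p": p,
            "q": q,
            "bound": bound,
        }
    )


def occupancy_table(
    annotation: GenomeAnnotation,
    readsets: Mapping[str, ReadSet],
    flank: int = 5000,
    q_threshold: float = 0.05,
    min_enrichment: float = 2.0,
) -> pd.DataFrame:
    """Convenience: windows + counting + binding calls for several factors,
    stacked into one long table."""
    windows = build_tss_windows(annotation, flank)
    tables = []
    for factor, rs in readsets.items():
        if rs.factor != factor:
            raise ValueError(f"readset factor {rs.factor!r} does not match key {factor!r}")
        counts = count_window_reads(windows, rs)
        tables.append(
            call_binding(counts, rs, windows, annotation.genome_size, q_threshold, min_enrichment)
        )
    return pd.concat(tables, ignore_index=True)


def bound_genes(occupancy: pd.DataFrame, factor: str) -> set[str]:
    sub = occupancy[occupancy["factor"] == factor]
    if sub.empty:
        raise KeyError(f"factor {factor!r} not in occupancy table")
    return set(sub.loc[sub["bound"], "gene_id"])


def call_targets(occupancy: pd.DataFrame, factor: str, polii: str = "POLII") -> set[str]:
    """Target genes of ``factor``: promoters bound by both POLII and the factor."""
    return bound_genes(occupancy, polii) & bound_genes(occupancy, factor)


@dataclass(frozen=True)
class OverlapStats:
    """Co-occupancy overlap between two target sets.

    Fractions are percentages; ``None`` marks an undefined fraction
    (empty reference set), which is deliberately distinct from 0.
    """

    n_a: int
    n_b: int
    n_intersection: int
    pct_a_in_b: float | None
    pct_b_in_a: float | None

    @classmethod
    def from_counts(cls, n_a: int, n_b: int, n_intersection: int) -> "OverlapStats":
        if n_intersection > min(n_a, n_b):
            raise ValueError("intersection larger than a set")
        return cls(
            n_a=n_a,
            n_b=n_b,
            n_intersection=n_intersection,
            pct_a_in_b=100.0 * n_intersection / n_a if n_a else None,
            pct_b_in_a=100.0 * n_intersection / n_b if n_b else None,
        )


def overlap_stats(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapStats:
    a, b = set(set_a), set(set_b)
    return OverlapStats.from_counts(len(a), len(b), len(a & b))


def quantile_normalize(matrix):
    """Classic quantile normalization across columns.

    Each column's rank-r value is replaced by the mean of the r-th order
    statistics across columns; ties receive the mean of the replacement
    values over their rank range. Column distributions are identical
    afterwards. Accepts a DataFrame or 2-D array; returns the same type.
    A single-column input is returned unchanged.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, k = arr.shape
    if k == 1:
        return matrix.copy()
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        out[order, j] = ref
        # average replacement values over tied ranks
        tied = pd.Series(out[:, j]).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class MetaProfile:
    """Mean read density around the TSS, strand-oriented.

    ``offsets`` are bin left edges in bp relative to the TSS (positive =
    downstream on the gene's strand); ``density`` is the mean per-window
    count per bin.
    """

    offsets: np.ndarray
    density: np.ndarray
    bin_size: int

    def to_frame(self, name: str = "density") -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, name: self.density})


def tss_metaprofile(
    readset: ReadSet,
    windows: Sequence[PromoterWindow],
    annotation: GenomeAnnotation,
    bin_size: int = 100,
) -> MetaProfile:
    """Mean strand-oriented read density per bin across all promoter windows."""
    mat = binned_profile_matrix(readset, windows, annotation, bin_size)
    flank = windows[0].flank
    offsets = np.arange(-flank, flank, bin_size)
    return MetaProfile(offsets=offsets, density=mat.mean(axis=0), bin_size=bin_size)


def binned_profile_matrix(
    readset: ReadSet,
    windows: Sequence[PromoterWindow],
    annotation: GenomeAnnotation,
    bin_size: int = 100,
) -> np.ndarray:
    """Windows × bins count matrix, with − strand windows reversed so that
    positive offsets are downstream of the TSS on the gene's strand."""
    if not windows:
        raise ValueError("no windows")
    flank = windows[0].flank
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must divide the full window span")
    n_bins = 2 * flank // bin_size
    strands = {r.gene_id: r.strand for r in annotation}
    mids = readset.by_chrom()
    mat = np.zeros((len(windows), n_bins), dtype=float)
    for i, win in enumerate(windows):
        pos = mids.get(win.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, win.tss - flank, side="left")
        hi = np.searchsorted(pos, win.tss + flank, side="left")
        offs = (pos[lo:hi] - win.tss).astype(np.int64)
        if strands[win.gene_id] == "-":
            # mirror so positive offsets are downstream on the gene's strand;
            # -x-1 maps [-flank, flank) onto itself (bin b -> n_bins-1-b)
            offs = -offs - 1
        keep = (offs >= -flank) & (offs < flank)
        idx = (offs[keep] + flank) // bin_size
        np.add.at(mat[i], idx, 1.0)
    return mat


def metaprofile_panel(
    readsets: Mapping[str, ReadSet],
    windows: Sequence[PromoterWindow],
    annotation: GenomeAnnotation,
    bin_size: int = 100,
    quantile: bool = True,
) -> pd.DataFrame:
    """Mean TSS profiles for several factors, optionally quantile-normalized
    across factors at the window×bin level before averaging (the Fig-2D-style
    view where factor densities are put on a common distribution)."""
    flank = windows[0].flank
    offsets = np.arange(-flank, flank, bin_size)
    mats = {
        factor: binned_profile_matrix(rs, windows, annotation, bin_size)
        for factor, rs in readsets.items()
    }
    factors = list(mats)
    if quantile and len(factors) > 1:
        flat = np.column_stack([mats[f].ravel() for f in factors])
        norm = quantile_normalize(flat)
        for j, f in enumerate(factors):
            mats[f] = norm[:, j].reshape(mats[f].shape)
    out = pd.DataFrame({"offset": offsets})
    for f in factors:
        out[f] = mats[f].mean(axis=0)
    return out


def write_target_set(targets: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(targets):
            fh.write(gene + "\n")


def read_target_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
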
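"""Transcriptional-amplification quantification for a target gene set.

Detects a global multiplicative increase of an actively transcribed gene
set's output: RPKM normalization, robust per-gene median/MAD scaling for
heatmap matrices, per-gene fold-increase summaries, and the rightward
shift of the cumulative log10(RPKM) distribution tested with Welch's
two-tailed t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix


def rpkm(
    counts: ExpressionMatrix,
    library_sizes: Sequence[float] | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase of gene model per million mapped reads.

    RPKM[g, s] = counts[g, s] × 1e9 / (length_g × library_size_s); library
    sizes default to the column sums of the count matrix.
    """
    if counts.units != "counts":
        raise ValueError("input must be in count units")
    vals = counts.values.to_numpy(dtype=float)
    if library_sizes is None:
        libs = vals.sum(axis=0)
    else:
        libs = np.asarray(library_sizes, dtype=float)
        if libs.shape != (vals.shape[1],):
            raise ValueError("one library size per sample required")
    if np.any(libs <= 0):
        raise ValueError("zero library size")
    lengths = counts.gene_lengths.to_numpy(dtype=float)
    out = vals * 1e9 / (lengths[:, None] * libs[None, :])
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        counts.gene_lengths,
        counts.conditions,
        units="rpkm",
    )


def mad_normalize(matrix: pd.DataFrame, eps: float = 1e-8) -> pd.DataFrame:
    """Per-row robust scaling: (x − median(x)) / MAD(x).

    MAD is the raw median absolute deviation (no Gaussian consistency
    factor). Rows with MAD 0 but non-constant residuals are divided by
    ``eps``; constant rows become all zeros.
    """
    arr = matrix.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a genes × samples matrix with >= 2 samples")
    med = np.median(arr, axis=1, keepdims=True)
    resid = arr - med
    mad = np.median(np.abs(resid), axis=1, keepdims=True)
    scale = mad.copy()
    zero_mad = mad[:, 0] == 0
    nonconstant = np.abs(resid).max(axis=1) > 0
    scale[zero_mad & nonconstant, 0] = eps
    scale[zero_mad & ~nonconstant, 0] = 1.0  # residuals are all zero anyway
    return pd.DataFrame(resid / scale, index=matrix.index, columns=matrix.columns)


@dataclass
class AmplificationSummary:
    """Fold-increase summary plus the distribution-shift test result."""

    folds: pd.Series | None = None
    n_undefined: int = 0
    max_fold: float | None = None
    mean_fold: float | None = None
    median_fold: float | None = None
    t: float | None = None
    df: float | None = None
    p: float | None = None
    n_a: int | None = None
    n_b: int | None = None
    cdf_tables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "max_fold": self.max_fold,
            "mean_fold": self.mean_fold,
            "median_fold": self.median_fold,
            "n_undefined_folds": self.n_undefined,
            "welch_t": self.t,
            "welch_df": self.df,
            "welch_p": self.p,
            "n_genes_a": self.n_a,
            "n_genes_b": self.n_b,
        }


def condition_means(expr: ExpressionMatrix, condition: str) -> pd.Series:
    cols = expr.samples_for(condition)
    if not cols:
        raise KeyError(f"no samples with condition {condition!r}")
    return expr.values[cols].mean(axis=1)


def fold_summary(
    expr: ExpressionMatrix,
    target_genes: Iterable[str],
    cond_a: str = "otosphere",
    cond_b: str = "imop",
    pseudocount: float = 0.0,
) -> AmplificationSummary:
    """Per-target-gene fold increase ``mean RPKM(cond_b) / mean RPKM(cond_a)``.

    Genes with a zero denominator are reported as undefined (NaN) and
    excluded from the max/mean/median with their count logged in
    ``n_undefined``.
    """
    if expr.units != "rpkm":
        raise ValueError("fold_summary expects RPKM units")
    targets = [g for g in target_genes]
    if not targets:
        raise ValueError("no target genes supplied")
    sub = expr.subset_genes(targets)
    a = condition_means(sub, cond_a) + pseudocount
    b = condition_means(sub, cond_b) + pseudocount
    folds = b / a
    folds[a == 0] = np.nan
    defined = folds.dropna()
    return AmplificationSummary(
        folds=folds,
        n_undefined=int(folds.isna().sum()),
        max_fold=float(defined.max()) if len(defined) else None,
        mean_fold=float(defined.mean()) if len(defined) else None,
        median_fold=float(defined.median()) if len(defined) else None,
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample two-tailed t on ``a`` vs ``b``: statistic,
    Welch–Satterthwaite df, p."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cdf_shift_test(
    expr: ExpressionMatrix,
    target_genes: Iterable[str],
    cond_a: str = "otosphere",
    cond_b: str = "imop",
    rpkm_range: tuple[float, float] = (1.0, 1e4),
) -> AmplificationSummary:
    """Cumulative-distribution shift of target-gene expression.

    Per condition, replicate RPKM are averaged per gene; genes are kept in
    a condition's CDF iff their condition-mean RPKM falls within
    ``rpkm_range`` (so a gene may appear in only one condition). Welch's
    two-tailed t is applied to the log10 values, cond_b minus cond_a, so a
    rightward shift in cond_b gives t > 0.
    """
    if expr.units != "rpkm":
        raise ValueError("cdf_shift_test expects RPKM units")
    sub = expr.subset_genes(target_genes)
    lo, hi = rpkm_range
    out = AmplificationSummary()
    logs = {}
    for cond in (cond_a, cond_b):
        m = condition_means(sub, cond)
        kept = m[(m >= lo) & (m <= hi)]
        if len(kept) < 2:
            raise ValueError(f"fewer than 2 genes in range for condition {cond!r}")
        vals = np.log10(kept.to_numpy())
        logs[cond] = vals
        x = np.sort(vals)
        logs[cond + "_cdf"] = pd.DataFrame(
            {"log10_rpkm": x, "cdf": np.arange(1, len(x) + 1) / len(x)}
        )
    t, df, p = welch_t(logs[cond_b], logs[cond_a])
    out.t, out.df, out.p = t, df, p
    out.n_a, out.n_b = len(logs[cond_a]), len(logs[cond_b])
    out.cdf_tables = {cond_a: logs[cond_a + "_cdf"], cond_b: logs[cond_b + "_cdf"]}
    return out
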
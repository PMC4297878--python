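"""Sample-level transcriptome comparison.

Spearman correlation between samples, average-linkage hierarchical
clustering on 1 − ρ, per-gene differential expression between two
conditions (Welch's t on log2(RPKM + pseudocount)), and hypergeometric
gene-set enrichment against a user-supplied term map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman ρ between sample columns (average-rank ties).

    Entries involving a constant sample (undefined ρ) are NaN; the
    diagonal is 1.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    corr = values.rank(axis=0, method="average").corr(method="pearson")
    constant = values.nunique(axis=0) <= 1
    for s in values.columns[constant]:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float


@dataclass
class Dendrogram:
    """Agglomeration result: ordered merges plus the induced leaf order."""

    merges: list[Merge]
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Ultrametric Newick string; a leaf's branch length is half the
        height of the merge that absorbs it."""
        node: dict[tuple[str, ...], str] = {}
        height: dict[tuple[str, ...], float] = {}
        for m in self.merges:
            for side in (m.left, m.right):
                if side not in node:
                    node[side] = side[0] if len(side) == 1 else node[side]
                    height[side] = 0.0
            bl_l = m.height / 2 - height[m.left] / 2
            bl_r = m.height / 2 - height[m.right] / 2
            key = tuple(sorted(m.left + m.right))
            node[key] = f"({node[m.left]}:{bl_l:.6g},{node[m.right]}:{bl_r:.6g})"
            height[key] = m.height
        root = tuple(sorted(self.leaf_order))
        return node.get(root, self.leaf_order[0]) + ";"

    def clades(self) -> list[frozenset[str]]:
        return [frozenset(m.left + m.right) for m in self.merges]


def hierarchical_cluster(corr: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration on distance d = 1 − ρ.

    Cluster–cluster distance is the mean of all original pairwise
    distances. Ties are broken deterministically by the lexicographically
    smallest pair of cluster name tuples, so the dendrogram is reproducible.
    """
    if not np.allclose(corr.values, corr.values.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if corr.isna().any().any():
        raise ValueError("correlation matrix contains undefined entries")
    d = 1.0 - corr
    clusters: list[tuple[str, ...]] = [(s,) for s in corr.columns]
    merges: list[Merge] = []
    order: dict[tuple[str, ...], list[str]] = {c: list(c) for c in clusters}

    def avg_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return float(d.loc[list(a), list(b)].to_numpy().mean())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                key = (avg_dist(a, b), a, b)
                if best is None or key < best:
                    best = key
        h, a, b = best
        merges.append(Merge(left=a, right=b, height=h))
        merged = tuple(sorted(a + b))
        order[merged] = order[a] + order[b]
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
    leaf_order = order[clusters[0]] if clusters else []
    return Dendrogram(merges=merges, leaf_order=leaf_order)


def filter_detectable(rpkm_values: pd.DataFrame, min_rpkm: float = 1.0) -> pd.DataFrame:
    """Genes considered detectable: RPKM ≥ ``min_rpkm`` in at least one sample."""
    return rpkm_values[(rpkm_values >= min_rpkm).any(axis=1)]


def differential_expression(
    rpkm_a: pd.DataFrame,
    rpkm_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression between two replicate groups.

    log2 fold change = log2((mean_b + pc) / (mean_a + pc)); Welch's t on
    log2(RPKM + pc) across replicates, two-tailed, BH-adjusted across
    genes. With a single replicate in either group only the fold change is
    emitted (t, p, q are NaN).
    """
    if list(rpkm_a.index) != list(rpkm_b.index):
        raise ValueError("gene sets of the two groups differ")
    mean_a = rpkm_a.mean(axis=1).to_numpy()
    mean_b = rpkm_b.mean(axis=1).to_numpy()
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    out = pd.DataFrame({"log2_fc": log2fc}, index=rpkm_a.index)
    if rpkm_a.shape[1] >= 2 and rpkm_b.shape[1] >= 2:
        la = np.log2(rpkm_a.to_numpy(dtype=float) + pseudocount)
        lb = np.log2(rpkm_b.to_numpy(dtype=float) + pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: equal means -> no evidence (t=0, p=1)
        degenerate = ~np.isfinite(t)
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        t[degenerate & equal] = 0.0
        p[degenerate & equal] = 1.0
        t[degenerate & ~equal] = np.inf * np.sign((lb.mean(axis=1) - la.mean(axis=1)))[
            degenerate & ~equal
        ]
        p[degenerate & ~equal] = np.nextafter(0, 1)
        out["t"] = t
        out["p"] = p
        out["q"] = multipletests(p, method="fdr_bh")[1]
    else:
        out["t"] = np.nan
        out["p"] = np.nan
        out["q"] = np.nan
    return out


def de_between_conditions(
    expr: ExpressionMatrix, cond_a: str, cond_b: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    if expr.units != "rpkm":
        raise ValueError("differential expression expects RPKM units")
    return differential_expression(
        expr.values[expr.samples_for(cond_a)],
        expr.values[expr.samples_for(cond_b)],
        pseudocount=pseudocount,
    )


def gene_set_enrichment(
    query_genes: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene list per term.

    ``term_map`` maps gene id → collection of term ids. p is the
    probability of drawing ≥ k term genes in a query of size n from a
    universe of size N containing K term genes; BH across terms.
    """
    query = set(query_genes)
    uni = set(universe)
    missing = query - uni
    if missing:
        raise ValueError(f"query genes absent from universe: {sorted(missing)[:5]}")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in uni:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    n, big_n = len(query), len(uni)
    for term, genes in sorted(term_genes.items()):
        big_k = len(genes)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "term_size": big_k, "overlap": k, "p": p})
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) → gene → set of terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out
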
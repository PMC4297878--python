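"""Bisulfite clone-sequencing analysis of a regulatory region.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T)
while methylated CpG cytosines stay C. Given a reference sequence and
gapless, equal-length Sanger clone sequences, this module locates CpG
sites, calls each clone×site cell methylated/unmethylated/ambiguous,
summarizes percent methylation, and renders a lollipop-style text grid.
Only the C of the CpG on the given strand is interpreted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "A"

_SYMBOLS = {METHYLATED: "●", UNMETHYLATED: "○", AMBIGUOUS: "·"}


def find_cpg_sites(reference_seq: str) -> list[int]:
    """0-based offsets i with reference[i] == 'C' and reference[i+1] == 'G'."""
    ref = reference_seq.upper()
    bad = set(ref) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return [i for i in range(len(ref) - 1) if ref[i] == "C" and ref[i + 1] == "G"]


def call_clone(reference_seq: str, clone_seq: str, sites: Sequence[int]) -> list[str]:
    """Methylation call at each CpG site of one clone.

    C → methylated (protected from conversion), T → unmethylated
    (converted), anything else → ambiguous.
    """
    if len(clone_seq) != len(reference_seq):
        raise ValueError(
            f"clone length {len(clone_seq)} != reference length {len(reference_seq)}"
        )
    clone = clone_seq.upper()
    calls = []
    for i in sites:
        base = clone[i]
        if base == "C":
            calls.append(METHYLATED)
        elif base == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)
    return calls


def call_clones(
    reference_seq: str, clone_seqs: dict[str, str] | Sequence[str]
) -> pd.DataFrame:
    """MethylationMatrix: clones × CpG sites with calls in {M, U, A}."""
    sites = find_cpg_sites(reference_seq)
    if isinstance(clone_seqs, dict):
        items = list(clone_seqs.items())
    else:
        items = [(f"clone_{i + 1}", s) for i, s in enumerate(clone_seqs)]
    rows = {name: call_clone(reference_seq, seq, sites) for name, seq in items}
    return pd.DataFrame.from_dict(rows, orient="index", columns=sites)


def methylation_summary(matrix: pd.DataFrame) -> tuple[int, int, float]:
    """(n_methylated, n_called, percent to one decimal).

    Ambiguous cells are excluded from the denominator.
    """
    if matrix.size == 0:
        raise ValueError("empty methylation matrix")
    flat = matrix.to_numpy().ravel()
    n_meth = int((flat == METHYLATED).sum())
    n_called = n_meth + int((flat == UNMETHYLATED).sum())
    if n_called == 0:
        raise ValueError("no called (non-ambiguous) cells")
    percent = round(100.0 * n_meth / n_called, 1)
    return n_meth, n_called, percent


def lollipop_matrix(matrix: pd.DataFrame) -> str:
    """Text grid, one row per clone: ● methylated, ○ unmethylated, · ambiguous."""
    lines = []
    for _, row in matrix.iterrows():
        lines.append("".join(_SYMBOLS[c] for c in row))
    return "\n".join(lines)


def read_region_fasta(path: str | Path) -> tuple[str, dict[str, str]]:
    """FASTA reader: first record is the reference, the rest are clones."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    ref = str(records[0].seq)
    clones = {rec.id: str(rec.seq) for rec in records[1:]}
    return ref, clones
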
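"""Synthetic data with recorded ground truth for every pipeline input.

The generators emulate the data the analysis assumes:

* a genome annotation with non-overlapping gene bodies and strand-aware
  TSSs;
* ChIP read intervals as a two-component mixture — read centers Normal
  around the TSSs of "bound" genes, over a uniform genomic background;
* negative-binomial RNA-seq counts in which a designated target-gene
  subset carries a multiplicative amplification factor in the iMOP-like
  condition (variance = mean + dispersion·mean², i.e. the
  (mean, dispersion) NB parameterization);
* bisulfite-converted clone sequences with per-CpG-site methylation
  probabilities and an explicit conversion rate;
* binomial labeled-cell counts and exponential growth series.

Seeding: one master seed. Each sub-simulator derives an independent
stream as ``SeedSequence([seed, crc32(label), ...])`` with a fixed string
label per stream ("genome", "truth", "chip"/<factor>, "expr", ...), so
adding or reordering simulators never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome import FACTORS, GeneRecord, GenomeAnnotation, ReadSet, write_chrom_sizes
from .methylation import find_cpg_sites

_MIN_GENE_LEN = 2_000
_MAX_GENE_LEN = 10_000
_TSS_MARGIN = 5_000  # keep TSSs >= 5 kb from chromosome ends


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Independent, stable random stream derived from the master seed."""
    keys = [zlib.crc32(str(label).encode()) for label in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analyzed design: 3 otosphere-like and 2 iMOP-like
    RNA-seq replicates, promoter ChIP enrichment concentrated within ~1 kb
    of the TSS, a 1.5× amplification of target genes in the iMOP-like
    condition, and 10 bisulfite clones over 15 CpG sites.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000_000})
    n_genes: int = 2_000
    seed: int = 0
    # ChIP
    chip_enrichment: float = 10.0
    chip_reads_per_factor: int = 200_000
    read_length: int = 50
    frag_sd: float = 500.0
    flank: int = 5_000
    # ground truth structure
    frac_target: float = 0.4
    frac_extra_bound: float = 0.1
    # RNA-seq
    expr_mean_log2: float = 5.0
    expr_sd_log2: float = 1.5
    expr_dispersion: float = 0.05
    amplification_factor: float = 1.5
    n_replicates: tuple[int, int] = (3, 2)  # (otosphere-like, iMOP-like)
    # bisulfite
    n_clones: int = 10
    n_cpg_sites: int = 15
    meth_prob_low: float = 0.02
    meth_prob_high: float = 0.807
    conversion_rate: float = 0.995

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.chip_enrichment < 0:
            raise ValueError("chip_enrichment must be >= 0")
        if self.expr_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.amplification_factor <= 0:
            raise ValueError("amplification_factor must be positive")
        if not (0 < self.conversion_rate <= 1):
            raise ValueError("conversion_rate must be in (0, 1]")
        for p in (self.meth_prob_low, self.meth_prob_high, self.frac_target, self.frac_extra_bound):
            if not (0 <= p <= 1):
                raise ValueError("probabilities/fractions must be in [0, 1]")
        if any(r < 1 for r in self.n_replicates):
            raise ValueError("need >= 1 replicate per condition")


@dataclass
class GroundTruth:
    """Recorded truth: bound promoters per factor, the POLII-anchored
    target set, and per-gene amplification multipliers."""

    bound_genes: dict[str, set[str]]
    target_genes: set[str]
    amplification: dict[str, float]

    def __post_init__(self):
        if not self.target_genes <= self.bound_genes.get("POLII", set()):
            raise ValueError("target genes must be POLII-bound")
        if not set(self.amplification) <= self.target_genes:
            raise ValueError("amplified genes must be target genes")
        if any(m <= 0 for m in self.amplification.values()):
            raise ValueError("amplification multipliers must be positive")


def simulate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place ``n_genes`` non-overlapping gene bodies across the chromosomes.

    Genes are allotted to chromosomes proportionally to length, each gene
    occupies its own slot (so bodies can never overlap), strands are drawn
    50/50, and every TSS ends up >= 5 kb from the chromosome ends.
    Deterministic given the config seed.
    """
    rng = substream(config.seed, "genome")
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    if config.n_genes == 0:
        return GenomeAnnotation([], config.chrom_sizes)
    # largest-remainder proportional allocation
    quota = config.n_genes * sizes / sizes.sum()
    alloc = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - alloc))[: config.n_genes - alloc.sum()]:
        alloc[i] += 1
    records: list[GeneRecord] = []
    gene_no = 0
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        usable = config.chrom_sizes[chrom] - 2 * _TSS_MARGIN
        slot = usable // k if k else 0
        if usable <= 0 or slot < _MIN_GENE_LEN:
            raise ValueError(
                f"cannot place {k} non-overlapping genes on {chrom} "
                f"(slot {slot} bp < minimum gene length {_MIN_GENE_LEN} bp)"
            )
        max_len = min(_MAX_GENE_LEN, slot)
        for i in range(k):
            length = int(rng.integers(_MIN_GENE_LEN, max_len + 1))
            offset = int(rng.integers(0, slot - length + 1))
            start = _TSS_MARGIN + i * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                GeneRecord(f"gene_{gene_no:05d}", chrom, start, start + length, strand)
            )
            gene_no += 1
    return GenomeAnnotation(records, config.chrom_sizes)


def simulate_ground_truth(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> GroundTruth:
    """Draw the true target set and per-factor bound promoter sets.

    ``frac_target`` of genes are bound by all three factors (the true
    POLII-anchored targets of both transcription factors); each factor
    additionally binds an independent ``frac_extra_bound`` share of the
    remaining genes. Every target carries the config amplification factor.
    """
    rng = substream(config.seed, "truth")
    ids = np.array(annotation.gene_ids)
    n = len(ids)
    n_target = int(round(config.frac_target * n))
    targets = set(rng.choice(ids, size=n_target, replace=False)) if n_target else set()
    rest = np.array(sorted(set(ids) - targets))
    bound: dict[str, set[str]] = {}
    n_extra = int(round(config.frac_extra_bound * n))
    for factor in FACTORS:
        extra = (
            set(rng.choice(rest, size=min(n_extra, len(rest)), replace=False))
            if n_extra and len(rest)
            else set()
        )
        bound[factor] = targets | extra
    return GroundTruth(
        bound_genes=bound,
        target_genes=targets,
        amplification={g: config.amplification_factor for g in targets},
    )


def simulate_chip_reads(
    annotation: GenomeAnnotation,
    ground_truth: GroundTruth,
    config: SimulationConfig,
    factor: str,
) -> ReadSet:
    """Two-component ChIP read mixture for one factor.

    A read center is, with probability
    ``e·n_bound·w / (e·n_bound·w + G)`` (``e`` = chip_enrichment, ``w`` =
    the 2·flank promoter-window mass, ``G`` = genome size), drawn as
    TSS + Normal(0, frag_sd) of a uniformly chosen bound gene; otherwise
    uniform over the genome. Fixed-length single-end intervals, clipped to
    chromosome bounds; exactly ``chip_reads_per_factor`` reads.
    """
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    rng = substream(config.seed, "chip", factor)
    total = config.chip_reads_per_factor
    bound = sorted(ground_truth.bound_genes.get(factor, set()))
    genome = annotation.genome_size
    w = 2.0 * config.flank
    mass_bound = config.chip_enrichment * len(bound) * w
    p_bound = mass_bound / (mass_bound + genome) if mass_bound > 0 else 0.0
    n_bound = int(rng.binomial(total, p_bound)) if p_bound > 0 else 0

    chrom_list = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chrom_list], dtype=float)

    centers = np.empty(total, dtype=np.int64)
    chrom_idx = np.empty(total, dtype=np.int64)
    if n_bound:
        by_id = {r.gene_id: r for r in annotation}
        tss = np.array([by_id[g].tss for g in bound], dtype=np.int64)
        gchrom = np.array([chrom_list.index(by_id[g].chrom) for g in bound], dtype=np.int64)
        pick = rng.integers(0, len(bound), size=n_bound)
        centers[:n_bound] = tss[pick] + np.round(
            rng.normal(0.0, config.frag_sd, size=n_bound)
        ).astype(np.int64)
        chrom_idx[:n_bound] = gchrom[pick]
    n_bg = total - n_bound
    if n_bg:
        ci = rng.choice(len(chrom_list), size=n_bg, p=sizes / sizes.sum())
        chrom_idx[n_bound:] = ci
        centers[n_bound:] = (rng.random(n_bg) * sizes[ci]).astype(np.int64)

    csize = np.array([config.chrom_sizes[c] for c in chrom_list], dtype=np.int64)[chrom_idx]
    starts = np.clip(centers - config.read_length // 2, 0, None)
    ends = np.minimum(starts + config.read_length, csize)
    starts = np.minimum(starts, ends - 1)  # keep intervals non-empty at the right edge
    chroms = np.array(chrom_list, dtype=object)[chrom_idx]
    return ReadSet(factor, chroms, starts, ends)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) draws with variance = mean + dispersion·mean²."""
    if dispersion <= 0:
        raise ValueError("NB dispersion must be positive")
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(
    annotation: GenomeAnnotation,
    ground_truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Count matrices for the otosphere-like and iMOP-like conditions.

    Per-gene baseline means are lognormal (log2 mean ``expr_mean_log2``,
    log2 sd ``expr_sd_log2``); iMOP-condition means of target genes are
    multiplied by their ground-truth amplification factor; counts are NB
    per replicate. Deterministic given the config seed.
    """
    rng = substream(config.seed, "expr")
    ids = annotation.gene_ids
    lengths = annotation.gene_lengths()
    base = 2.0 ** rng.normal(config.expr_mean_log2, config.expr_sd_log2, size=len(ids))
    amp = np.array([ground_truth.amplification.get(g, 1.0) for g in ids])
    n_oto, n_imop = config.n_replicates
    oto = np.column_stack(
        [_nb_counts(rng, base, config.expr_dispersion) for _ in range(n_oto)]
    )
    imop = np.column_stack(
        [_nb_counts(rng, base * amp, config.expr_dispersion) for _ in range(n_imop)]
    )
    m_oto = ExpressionMatrix(
        pd.DataFrame(oto, index=ids, columns=[f"otosphere.{i + 1}" for i in range(n_oto)]),
        lengths,
        ["otosphere"] * n_oto,
        units="counts",
    )
    m_imop = ExpressionMatrix(
        pd.DataFrame(imop, index=ids, columns=[f"imop.{i + 1}" for i in range(n_imop)]),
        lengths,
        ["imop"] * n_imop,
        units="counts",
    )
    return m_oto, m_imop


def simulate_outgroup_expression(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    n_samples: int = 1,
    condition: str = "esc",
) -> ExpressionMatrix:
    """ESC-like outgroup samples with an independently drawn expression
    program (fresh lognormal baseline means), for clustering-topology
    checks."""
    rng = substream(config.seed, "expr", condition)
    ids = annotation.gene_ids
    base = 2.0 ** rng.normal(config.expr_mean_log2, config.expr_sd_log2, size=len(ids))
    counts = np.column_stack(
        [_nb_counts(rng, base, config.expr_dispersion) for _ in range(n_samples)]
    )
    return ExpressionMatrix(
        pd.DataFrame(
            counts, index=ids, columns=[f"{condition}.{i + 1}" for i in range(n_samples)]
        ),
        annotation.gene_lengths(),
        [condition] * n_samples,
        units="counts",
    )


@dataclass
class BisulfiteClones:
    """Simulated clone sequences plus the true methylation states."""

    sequences: list[str]
    states: np.ndarray  # clones × sites, bool: True = methylated
    sites: list[int]


def simulate_bisulfite_clones(
    reference_seq: str,
    site_meth_probs: Sequence[float],
    n_clones: int,
    conversion_rate: float = 1.0,
    seed: int = 0,
) -> BisulfiteClones:
    """Bisulfite-converted clone sequences from a reference region.

    For each clone and CpG site, the cytosine is methylated with the
    site's probability. Methylated CpG cytosines are retained as C;
    unmethylated cytosines (CpG or not) convert C→T with probability
    ``conversion_rate``.
    """
    if not (0 < conversion_rate <= 1):
        raise ValueError("conversion_rate must be in (0, 1]")
    ref = reference_seq.upper()
    sites = find_cpg_sites(ref)
    probs = np.asarray(site_meth_probs, dtype=float)
    if probs.shape != (len(sites),):
        raise ValueError(
            f"need one methylation probability per CpG site: {len(sites)} sites, "
            f"{probs.size} probabilities"
        )
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("methylation probabilities must be in [0, 1]")
    rng = substream(seed, "bisulfite")
    site_set = dict(zip(sites, range(len(sites))))
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    states = rng.random((n_clones, len(sites))) < probs[None, :]
    sequences = []
    for ci in range(n_clones):
        seq = list(ref)
        for pos in c_positions:
            j = site_set.get(pos)
            methylated = j is not None and states[ci, j]
            if not methylated and rng.random() < conversion_rate:
                seq[pos] = "T"
        sequences.append("".join(seq))
    return BisulfiteClones(sequences=sequences, states=states, sites=sites)


def make_cpg_reference(
    n_sites: int = 15, spacing: int = 12, seed: int = 0
) -> str:
    """Random reference sequence containing exactly ``n_sites`` CpG
    dinucleotides at regular spacing (a synthetic stand-in for the Oct4
    upstream regulatory region)."""
    rng = substream(seed, "reference")
    length = spacing * (n_sites + 1)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    for i in range(length - 1):  # break accidental CpGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    positions = [spacing * (k + 1) for k in range(n_sites)]
    for p in positions:
        seq[p], seq[p + 1] = "C", "G"
    ref = "".join(seq)
    assert find_cpg_sites(ref) == positions
    return ref


def simulate_growth_series(
    doubling_hr: float = 18.0,
    n_weeks: int = 10,
    initial_count: float = 1e4,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weekly cumulative counts for exponential growth with multiplicative
    lognormal noise (sd on the natural-log scale)."""
    rng = substream(seed, "growth")
    t = np.arange(n_weeks + 1) * 168.0  # hours
    counts = initial_count * 2.0 ** (t / doubling_hr)
    counts = counts * np.exp(rng.normal(0.0, noise_sd, size=len(t)))
    return t, counts


# --------------------------------------------------------------------- I/O


def write_ground_truth(truth: GroundTruth, annotation: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for g in annotation.gene_ids:
        rows.append(
            {
                "gene_id": g,
                **{f"bound_{f}": int(g in truth.bound_genes.get(f, set())) for f in FACTORS},
                "target": int(g in truth.target_genes),
                "amplification": truth.amplification.get(g, 1.0),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    bound = {f: set(df.loc[df[f"bound_{f}"] == 1, "gene_id"]) for f in FACTORS}
    targets = set(df.loc[df["target"] == 1, "gene_id"])
    amp = {
        g: float(a)
        for g, a, t in zip(df["gene_id"], df["amplification"], df["target"])
        if t == 1
    }
    return GroundTruth(bound_genes=bound, target_genes=targets, amplification=amp)


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_simulation(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_genome(config)
    truth = simulate_ground_truth(annotation, config)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(config.chrom_sizes, paths["chrom_sizes"])
    paths["annotation"] = outdir / "annotation.bed"
    annotation.write_bed(paths["annotation"])
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    write_ground_truth(truth, annotation, paths["ground_truth"])

    for factor in FACTORS:
        reads = simulate_chip_reads(annotation, truth, config, factor)
        key = f"reads_{factor}"
        paths[key] = outdir / f"reads_{factor.replace('-', '')}.bed"
        reads.write_bed(paths[key])

    oto, imop = simulate_expression(annotation, truth, config)
    paths["counts"] = outdir / "counts.tsv"
    oto.concat(imop).write_tsv(paths["counts"])

    ref = make_cpg_reference(config.n_cpg_sites, seed=config.seed)
    for label, prob in (("esc", config.meth_prob_low), ("imop", config.meth_prob_high)):
        clones = simulate_bisulfite_clones(
            ref,
            [prob] * config.n_cpg_sites,
            config.n_clones,
            config.conversion_rate,
            seed=config.seed + (0 if label == "esc" else 1),
        )
        recs = {"reference": ref}
        recs.update(
            {f"{label}_clone_{i + 1}": s for i, s in enumerate(clones.sequences)}
        )
        key = f"bisulfite_{label}"
        paths[key] = outdir / f"bisulfite_{label}.fa"
        write_fasta(recs, paths[key])
    return paths
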
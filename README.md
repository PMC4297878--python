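# ampscan

Regulatory-genomics toolkit for detecting **transcriptional amplification**
of a transcription factor's target genes, built around the biology of
immortalized multipotent otic progenitor (iMOP) cells — inner-ear
progenitors in which C-MYC globally amplifies the output of SOX2-dependent
transcripts. The package is aimed at analysts who start from aligned ChIP
read intervals and gene-level RNA-seq counts and want a reproducible,
fully testable path from promoter occupancy to an amplification call.

## What it computes

**Promoter occupancy and target genes.** For each gene the promoter is the
±5 kb window around its strand-aware TSS. A factor (RNA POLII, C-MYC,
SOX2) is called *bound* when its window read count exceeds the
uniform-background Poisson expectation

λ_g = N · w_g / G  (N reads, w_g window length, G genome size)

with a Benjamini–Hochberg FDR q < 0.05 **and** fold enrichment
count/λ ≥ 2. A factor's **target genes** are genes whose promoters are
bound by both RNA POLII and that factor; co-occupancy is summarized as
|A∩B| and the percentage of each target set occupied by the other factor.
Quantile-normalized, strand-oriented TSS metaprofiles give the ±5 kb
density view.

**Transcriptional amplification.** Expression is normalized to RPKM
(counts · 10⁹ / (length · library size)). For a heatmap-ready matrix each
gene row is robustly scaled as (x − median)/MAD. Amplification of a
target set is quantified as per-gene fold increases (iMOP/otosphere means)
and as a rightward shift of the cumulative distribution of
log₁₀(RPKM) within 1–10⁴ RPKM, tested with Welch's two-tailed t.

**Transcriptome comparison.** Spearman correlation between samples,
average-linkage clustering on 1 − ρ with deterministic tie-breaking,
Welch-based pairwise differential expression on log₂(RPKM+1), and
hypergeometric gene-set enrichment against a user-supplied gene→term map.

**Bisulfite methylation.** CpG detection, per-clone methylated /
unmethylated / ambiguous calls (C retained vs C→T converted), lollipop
text grids, and percent methylation.

**Small-sample quantifications.** Labeled-cell fractions with Wilson 95%
CIs, population composition, transcript-fraction partitioning, and
growth-curve doubling time by log-linear regression.

A synthetic-data module generates **every** input with recorded ground
truth (bound promoter sets, amplification multipliers, per-site
methylation states), so the whole pipeline is testable end to end without
external data.

## Worked example

Run the bundled end-to-end pipeline (simulate → occupancy → targets →
overlap → amplification) on the default cohort of 2,000 genes with a true
1.5× amplification of 40% of genes:

```bash
ampscan run --seed 1 --out run1
```

The report (`run1/report.json`) contains, among other keys:

```json
"targets":  {"SOX2": 835, "C-MYC": 843, "both": 805},
"overlap":  {"pct_sox2_also_cmyc": 96.4},
"fold":     {"max": 2.90, "mean": 1.31, "median": 1.26},
"shift":    {"t": 4.18, "df": 1607.97, "p": 3.1e-05}
```

Reading: 835 genes are called SOX2 targets (promoter bound by both POLII
and SOX2), 96.4% of them are also C-MYC targets, and the 805 shared
targets show a significant rightward shift of their RPKM distribution in
the iMOP-like condition (Welch p ≈ 3×10⁻⁵). The median fold (1.26) sits
below the simulated 1.5× because library-size normalization absorbs part
of a global amplification — see `docs/methods.md`.

Individual stages are also available:

```bash
ampscan stats fraction 956 1036 --decimals 0   # -> {"percent": 92.0, ...}
ampscan stats composition 11 30 12             # -> [21, 57, 23]
ampscan chip call-targets --annotation ... --reads-polii ... --reads-factor ...
ampscan amp shift --counts counts.tsv --targets targets.txt
ampscan meth --fasta region.fa
```

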
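# Methods

This note documents the models, statistical rules, defaults and
numerical choices behind `ampscan`, and what its synthetic data do and do
not establish about real data.

## Promoter occupancy model

The promoter of a gene is the ±`flank` (default 5,000 bp) window around
its strand-aware TSS: the `start` of a `+` strand gene, `end − 1` of a
`−` strand gene, with 0-based half-open coordinates throughout. Windows
are clamped to chromosome bounds, but the background expectation keeps
the *nominal* 2·flank length so edge genes are not artificially enriched.

Reads are assigned to windows by their midpoint (`[win_start, win_end)`,
half-open); a read may count toward several overlapping windows. Midpoint
assignment makes each read's window membership unambiguous and
insensitive to read length.

Binding is called per factor by a Poisson test against a uniform-genome
background: λ_g = N·w/G, p_g = P(Poisson(λ_g) ≥ count_g),
Benjamini–Hochberg across genes, bound ⇔ q < 0.05 and count/λ ≥ 2. No
standard peak caller encodes exactly this promoter-window decision; the
rule was chosen as the simplest defensible model that is fully
reproducible from first principles. The minimum-enrichment gate guards
against the huge-sample regime where trivial enrichments become
significant. The uniform background is deliberately conservative
for bound-region inference when a large fraction of reads is
promoter-concentrated: the genome-wide rate then overstates the
background, which depresses false positives at unbound promoters.

Target genes of a factor are genes bound by both RNA POLII and the
factor. Overlap statistics report exact counts and percentages; the
fraction "of A in B" for an empty A is reported as an explicit undefined
marker, never 0.

### Quantile normalization

Classic column-wise quantile normalization: rank each column, replace the
r-th ranked value everywhere by the mean of the r-th order statistics
across columns. Ties receive the mean of the replacement values across
their rank range. With ties, the post-normalization column distributions
agree only up to the tie structure; the "sorted columns identical"
invariant is exact for tie-free columns. TSS metaprofiles can be quantile
normalized across factors at the window×bin level before averaging, which
puts factor densities on a common distribution; `−` strand windows are
mirrored (offset x → −x−1, an exact bijection of the ±flank span) so
positive offsets always mean downstream of the TSS.

## Transcriptional amplification

RPKM[g,s] = counts[g,s]·10⁹ / (length_g · library_size_s), with library
sizes defaulting to column sums. An important consequence, documented
rather than hidden: when a large gene subset is globally amplified,
column-sum library sizes grow with it, so per-gene RPKM folds are
attenuated below the true multiplier (with 40% of genes amplified 1.5×,
the expected observed fold is ≈1.5/1.2 = 1.25). This is intrinsic to any
per-library normalization and is why global amplification is famously
easy to miss; detection of the *distribution shift* remains powerful.
Generator-calibration tests that check recovery of the simulated
multiplier therefore use depth-matched (explicitly equal) library sizes.

Heatmap rows are scaled as (x − median(x))/MAD(x) with the raw MAD (no
1.4826 Gaussian-consistency factor — the intent is the literal robust
residual, not a variance estimate). Rows with MAD 0 but non-constant
residuals are divided by a small ε (10⁻⁸) to preserve ordering; fully
constant rows become zeros.

The cumulative-distribution shift test averages replicate RPKM per gene
within each condition, keeps genes whose condition mean lies in
[1, 10⁴] RPKM (applied per condition, so a gene can enter one CDF only),
and applies Welch's two-tailed t to the log₁₀ values, iMOP minus
otosphere. The log scale matches the decade-spanning, heavy-tailed RPKM
distribution; on the raw scale the test would be driven by a handful of
extreme genes. Under the no-amplification null the two condition-mean
vectors share the same per-gene baselines, so the cross-gene Welch test
is *conservative* (empirical rejection ≈ 0 at α = 0.05 over 200 seeds)
rather than exactly uniform in p; the test's t is exactly antisymmetric
under swapping condition labels. Fold summaries exclude zero-denominator
genes from max/mean/median and log their count.

## Transcriptome comparison

Spearman ρ is computed on average-tie ranks; entries involving a constant
sample are undefined (NaN). Clustering is average-linkage (UPGMA) on
d = 1 − ρ with cluster–cluster distance the mean of all original pairwise
distances; ties are broken by the lexicographically smallest pair of
cluster name tuples, making the dendrogram (and its Newick export)
deterministic. On tie-free inputs the merge heights coincide with scipy's
average-linkage, which the tests use as an independent cross-check.

Differential expression uses Welch's t on log₂(RPKM+1) across replicates
with BH adjustment — self-contained and consistent with the Welch
machinery used elsewhere; count-model tests (NB/exact) would import a
fitted dispersion model the pipeline does not otherwise need. With a
single replicate in a group only fold changes are emitted. "Detectable"
transcripts for clustering default to RPKM ≥ 1 in at least one sample.
Gene-set enrichment is the hypergeometric upper tail of the overlap
between a query and each term's gene set, BH across terms; the gene→term
map is always a user input (annotation databases are version-dependent,
so none is fetched or bundled).

## Bisulfite methylation

Clones are assumed gapless and equal-length with the reference (Sanger
clone sequencing of a short regulatory region; alignment is out of
scope). At each CpG cytosine: C ⇒ methylated (protected), T ⇒
unmethylated (converted), anything else ⇒ ambiguous. Only the C of the
CpG on the given strand is inspected. Percent methylation excludes
ambiguous cells from the denominator and is reported to one decimal.
Incomplete conversion (rate c < 1) leaves unmethylated Cs reading as C
and inflates observed methylation by (1−c)(1−p) in expectation at true
rate p — verified by simulation and bounded in the tests.

## Small-sample quantifications

Percentages round half-to-even at the stated decimals. Labeled-cell
fractions carry a Wilson score 95% CI (which always contains the point
estimate and stays inside [0, 100]). Composition percentages are rounded
to whole percent independently and may not sum to 100; they are reported
as-is. Doubling time is 1/slope of a least-squares fit of log₂(count)
against hours over all points — using the whole series rather than one
interval; slopes below 10⁻⁹ /hr are reported as undefined (non-growing).

## Synthetic data: what it emulates, and what it does not

One master seed drives everything; each sub-simulator derives an
independent stream as `SeedSequence([seed, crc32(label)])` with fixed
labels, so streams never shift when other components change.

* **Genome** — genes are allotted to chromosomes proportionally to
  length and placed in disjoint slots (non-overlap by construction),
  strands 50/50, lengths uniform 2–10 kb, TSSs ≥ 5 kb from chromosome
  ends. Defaults: 2,000 genes on one 100 Mb chromosome.
* **Ground truth** — 40% of genes are bound by all three factors (the
  true targets, each carrying the amplification multiplier); each factor
  binds an extra independent 10% of the remaining genes.
* **ChIP reads** — fixed-length (50 bp) single-end intervals; a read
  center is promoter-derived (TSS + Normal(0, 500 bp) of a uniformly
  chosen bound gene) with probability e·n·w/(e·n·w+G), else uniform.
  A 500 bp spread reproduces a unimodal concentration of signal within
  ~1 kb of the TSS with a single parameter. Defaults: enrichment e = 10,
  200,000 reads per factor — enough depth that promoter counts separate
  cleanly from λ ≈ 20.
* **RNA-seq** — per-gene lognormal baselines (log₂ mean 5, sd 1.5, i.e.
  a realistic several-decade dynamic range), NB counts with
  var = μ + 0.05·μ², 3 otosphere-like + 2 iMOP-like replicates
  (mirroring the analyzed design), targets multiplied by 1.5 in the iMOP
  condition. An ESC-like outgroup redraws its baseline program
  independently, giving low Spearman ρ to both otic conditions while the
  otic conditions stay at ρ ≈ 0.9 — the regime in which the clustering
  check is meaningful.
* **Bisulfite** — 10 clones over a 15-CpG synthetic reference (150 CpG
  calls per condition), site methylation probabilities 0.02 (ESC-like)
  and 0.807 (iMOP-like), conversion rate 0.995 by default.
* **Growth** — weekly counts over 10 weeks, 18 h doubling, 5%
  multiplicative noise.

Not emulated: sequencing errors and quality, PCR duplicates, paired-end
fragment-size distributions, GC/mappability bias, isoforms, batch
effects, enhancer (non-promoter) binding, and bisulfite read alignment.
Passing tests therefore demonstrate correctness of the statistical
machinery and calibration under the stated generative model — not
robustness to those real-data artifacts.

## Problem sizes

The default test suite and the acceptance script run the full-size
target-recovery simulation (2,000 genes, 3×200,000 reads), 100 + 200
seeds of the shift test for power and null calibration, 20 seeds of the
clustering topology check, and smaller cohorts (200–500 genes, 20–50 k
reads) for unit-level properties — sizes chosen so each property is
measured at adequate precision while a complete run stays in the tens of
seconds.

## Known limitations

* The Poisson background ignores chromatin accessibility and copy-number
  structure; on real data an input/IgG control track would replace G as
  the background model.
* RPKM fold attenuation under broad amplification (above) means absolute
  multipliers need spike-ins or depth-matched designs; this package only
  claims detection of the shift.
* Welch-based DE on log RPKM is underpowered at very low counts compared
  with count-model tests.
* Quantile normalization with heavy ties only equalizes distributions up
  to the tie structure.
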
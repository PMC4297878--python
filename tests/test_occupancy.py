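"""Promoter windows, binding calls, overlap statistics, metaprofiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampscan.genome import GeneRecord, GenomeAnnotation, ReadSet
from ampscan.occupancy import (
    OverlapStats,
    build_tss_windows,
    call_binding,
    call_targets,
    count_window_reads,
    metaprofile_panel,
    occupancy_table,
    overlap_stats,
    quantile_normalize,
    tss_metaprofile,
)
from ampscan.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_chip_reads,
    simulate_genome,
    simulate_ground_truth,
)


def _uniform_reads(rng, n, chrom_size, read_len=50, factor="POLII"):
    starts = rng.integers(0, chrom_size - read_len, size=n)
    return ReadSet(factor, ["chr1"] * n, starts, starts + read_len)


class TestWindows:
    def test_plus_strand_definition(self, toy_annotation):
        win = {w.gene_id: w for w in build_tss_windows(toy_annotation, flank=5_000)}
        w = win["gA"]  # + strand chr1:10,000-20,000
        assert (w.win_start, w.win_end, w.tss) == (5_000, 15_000, 10_000)

    def test_minus_strand_definition(self, toy_annotation):
        w = {w.gene_id: w for w in build_tss_windows(toy_annotation, flank=5_000)}["gB"]
        # - strand chr1:40,000-50,000 -> TSS = end - 1
        assert (w.win_start, w.win_end, w.tss) == (44_999, 54_999, 49_999)

    def test_boundary_clamp(self, toy_annotation):
        w = {w.gene_id: w for w in build_tss_windows(toy_annotation, flank=5_000)}["gC"]
        assert (w.win_start, w.win_end, w.tss) == (0, 8_000, 3_000)
        assert w.nominal_length == 10_000  # lambda uses the unclamped span

    def test_flank_must_be_positive(self, toy_annotation):
        with pytest.raises(ValueError):
            build_tss_windows(toy_annotation, flank=0)


class TestCounting:
    def test_empty_readset(self, toy_annotation):
        windows = build_tss_windows(toy_annotation)
        rs = ReadSet("POLII", [], [], [])
        assert count_window_reads(windows, rs).tolist() == [0, 0, 0]

    def test_half_open_convention(self, toy_annotation):
        windows = [w for w in build_tss_windows(toy_annotation) if w.gene_id == "gA"]
        # gA window is [5,000, 15,000); midpoints exactly at the edges
        rs = ReadSet(
            "POLII",
            ["chr1"] * 3,
            [14_975, 4_975, 14_974],  # midpoints 15,000 (out), 5,000 (in), 14,999 (in)
            [15_025, 5_025, 15_024],
        )
        assert count_window_reads(windows, rs).tolist() == [2]

    def test_matches_brute_force_scan(self):
        """Random overlapping 10 kb windows + 1e5 uniform reads: counts
        equal the O(n*m) per-read oracle exactly."""
        rng = np.random.default_rng(17)
        chrom_size = 5_000_000
        ann_records = []
        starts = rng.integers(10_000, chrom_size - 20_000, size=200)
        for i, s in enumerate(starts):
            ann_records.append(GeneRecord(f"g{i}", "chr1", int(s), int(s) + 2_000, "+"))
        ann = GenomeAnnotation(ann_records, {"chr1": chrom_size})
        windows = build_tss_windows(ann, flank=5_000)
        rs = _uniform_reads(rng, 100_000, chrom_size)
        fast = count_window_reads(windows, rs)
        mids = rs.midpoints()
        brute = np.array(
            [np.sum((mids >= w.win_start) & (mids < w.win_end)) for w in windows]
        )
        assert np.array_equal(fast, brute)


class TestCallBinding:
    def test_zero_count_unbound(self, toy_annotation):
        windows = build_tss_windows(toy_annotation)
        rs = ReadSet("POLII", ["chr1"], [50_000], [50_050])
        occ = call_binding(np.array([0, 1, 0]), rs, windows, 100_000)
        row = occ[occ.gene_id == "gA"].iloc[0]
        assert row.p == 1.0 and not row.bound

    def test_enrichment_ratio_gate(self):
        """A count exactly at lambda has enrichment 1 < 2 and is unbound
        regardless of p."""
        ann = GenomeAnnotation(
            [GeneRecord("g", "chr1", 50_000, 60_000, "+")], {"chr1": 100_000}
        )
        windows = build_tss_windows(ann)
        rs = ReadSet("POLII", ["chr1"] * 100, [0] * 100, [50] * 100)
        # lambda = 100 * 10,000 / 100,000 = 10
        occ = call_binding(np.array([10]), rs, windows, 100_000, q_threshold=0.999)
        assert occ.iloc[0].enrichment == 1.0
        assert not occ.iloc[0].bound

    def test_poisson_tail_brute_force(self):
        """P(Poisson(5) >= 25) from the library matches direct summation
        to 1e-12."""
        ann = GenomeAnnotation(
            [GeneRecord("g", "chr1", 50_000, 60_000, "+")], {"chr1": 200_000}
        )
        windows = build_tss_windows(ann)
        rs = ReadSet("POLII", ["chr1"] * 100, [0] * 100, [50] * 100)
        # lambda = 100 * 10,000 / 200,000 = 5
        occ = call_binding(np.array([25]), rs, windows, 200_000)
        expected = 1.0 - sum(math.exp(-5) * 5**k / math.factorial(k) for k in range(25))
        assert abs(occ.iloc[0].p - expected) < 1e-12

    def test_bh_monotone_and_bounded(self, small_annotation, small_truth, small_config):
        rs = simulate_chip_reads(small_annotation, small_truth, small_config, "POLII")
        occ = occupancy_table(small_annotation, {"POLII": rs})
        srt = occ.sort_values("p")
        assert srt["q"].is_monotonic_increasing
        assert ((occ["q"] >= occ["p"] - 1e-15) & (occ["q"] <= 1.0)).all()


@pytest.fixture(scope="module")
def occ(small_annotation, small_truth, small_config):
    readsets = {
        f: simulate_chip_reads(small_annotation, small_truth, small_config, f)
        for f in ("POLII", "C-MYC", "SOX2")
    }
    return occupancy_table(small_annotation, readsets)


class TestTargets:
    def test_targets_subset_of_bound(self, occ):
        from ampscan.occupancy import bound_genes

        for factor in ("C-MYC", "SOX2"):
            t = call_targets(occ, factor)
            assert t <= bound_genes(occ, factor)
            assert t <= bound_genes(occ, "POLII")

    def test_polii_bound_nowhere(self, occ):
        muted = occ.copy()
        muted.loc[muted.factor == "POLII", "bound"] = False
        assert call_targets(muted, "SOX2") == set()

    def test_factor_everywhere_polii_is(self, occ):
        from ampscan.occupancy import bound_genes

        forced = occ.copy()
        polii = bound_genes(occ, "POLII")
        forced.loc[forced.gene_id.isin(polii) & (forced.factor == "SOX2"), "bound"] = True
        assert call_targets(forced, "SOX2") == polii

    def test_missing_factor_errors(self, occ):
        with pytest.raises(KeyError):
            call_targets(occ, "KLF4")

    def test_null_false_positive_rate(self):
        """With no bound genes at all, the expected false-positive target
        rate stays below the q threshold (50 seeds)."""
        rates = []
        for seed in range(50):
            cfg = SimulationConfig(
                chrom_sizes={"chr1": 10_000_000},
                n_genes=200,
                seed=seed,
                chip_reads_per_factor=20_000,
            )
            ann = simulate_genome(cfg)
            truth = GroundTruth(
                bound_genes={f: set() for f in ("POLII", "C-MYC", "SOX2")},
                target_genes=set(),
                amplification={},
            )
            readsets = {
                f: simulate_chip_reads(ann, truth, cfg, f) for f in ("POLII", "SOX2")
            }
            occ = occupancy_table(ann, readsets)
            rates.append(len(call_targets(occ, "SOX2")) / len(ann))
        assert np.mean(rates) <= 0.05


class TestOverlap:
    def test_printed_counts_round_to_85(self):
        ov = OverlapStats.from_counts(4_994, 5_422, 4_231)
        assert round(ov.pct_a_in_b) == 85
        assert abs(ov.pct_a_in_b - 84.7) < 0.05

    def test_identical_sets(self):
        ov = overlap_stats({"a", "b"}, {"a", "b"})
        assert ov.pct_a_in_b == 100.0 and ov.pct_b_in_a == 100.0

    def test_disjoint_sets(self):
        ov = overlap_stats({"a"}, {"b"})
        assert ov.pct_a_in_b == 0.0 and ov.n_intersection == 0

    def test_empty_a_is_undefined_not_zero(self):
        ov = overlap_stats(set(), {"b"})
        assert ov.pct_a_in_b is None
        assert ov.pct_b_in_a == 0.0

    @given(
        a=st.sets(st.integers(0, 50), max_size=30),
        b=st.sets(st.integers(0, 50), max_size=30),
    )
    @settings(max_examples=50, derandomize=True)
    def test_intersection_symmetric(self, a, b):
        sa = {str(x) for x in a}
        sb = {str(x) for x in b}
        assert overlap_stats(sa, sb).n_intersection == overlap_stats(sb, sa).n_intersection


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = np.column_stack([[3.0, 1.0, 2.0]] * 3)
        assert np.allclose(quantile_normalize(m), m)

    def test_hand_computed_two_columns(self):
        m = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = quantile_normalize(m)
        assert np.allclose(out[:, 0], [5.5, 11.0, 16.5])
        assert np.allclose(out[:, 1], [5.5, 11.0, 16.5])

    def test_ties_get_rank_range_mean(self):
        m = np.array([[1.0, 10.0], [1.0, 20.0], [3.0, 30.0]])
        out = quantile_normalize(m)
        # reference = (5.5, 10.5, 16.5); tied pair averages first two
        assert np.allclose(out[:, 0], [8.0, 8.0, 16.5])

    def test_single_column_unchanged(self):
        m = np.array([[4.0], [1.0]])
        assert np.allclose(quantile_normalize(m), m)

    @given(
        vals=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=8, max_size=24, unique=True
        ).filter(lambda v: len(v) % 4 == 0)
    )
    @settings(max_examples=50, derandomize=True)
    def test_sorted_columns_identical_after(self, vals):
        # tie-free columns: with ties the averaged replacement values are
        # shared within a column, so exact equality holds only untied
        m = np.array(vals, dtype=float).reshape(-1, 4)
        out = quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref)


class TestMetaprofile:
    def test_uniform_reads_flat(self, small_annotation):
        rng = np.random.default_rng(3)
        rs = _uniform_reads(rng, 200_000, 20_000_000)
        windows = build_tss_windows(small_annotation)
        prof = tss_metaprofile(rs, windows, small_annotation, bin_size=500)
        n_win = len(windows)
        # each window x bin cell is ~Binomial(n, bin/G)
        p = 500 / 20_000_000
        mean = 200_000 * p
        sd = np.sqrt(200_000 * p * (1 - p) / n_win)
        assert np.all(np.abs(prof.density - mean) < 4 * sd)

    def test_peak_at_tss(self, small_annotation, small_config):
        cfg = SimulationConfig(
            chrom_sizes=small_config.chrom_sizes,
            n_genes=small_config.n_genes,
            seed=13,
            chip_enrichment=50.0,
            chip_reads_per_factor=100_000,
            frag_sd=500.0,
        )
        truth = simulate_ground_truth(small_annotation, cfg)
        rs = simulate_chip_reads(small_annotation, truth, cfg, "POLII")
        windows = build_tss_windows(small_annotation)
        prof = tss_metaprofile(rs, windows, small_annotation, bin_size=100)
        peak_offset = prof.offsets[np.argmax(prof.density)]
        assert abs(peak_offset + 50) <= 150  # bin containing 0, +/- 1 bin

    def test_strand_flip_mirrors_profile(self, small_annotation, small_truth, small_config):
        rs = simulate_chip_reads(small_annotation, small_truth, small_config, "POLII")
        windows = build_tss_windows(small_annotation)
        flipped = GenomeAnnotation(
            [
                GeneRecord(r.gene_id, r.chrom, r.start, r.end,
                           "-" if r.strand == "+" else "+")
                for r in small_annotation
            ],
            small_annotation.chrom_sizes,
        )
        # same physical windows, flipped strand assignment only
        prof = tss_metaprofile(rs, windows, small_annotation, bin_size=100)
        prof_flip = tss_metaprofile(rs, windows, flipped, bin_size=100)
        assert np.allclose(prof.density, prof_flip.density[::-1])

    def test_panel_quantile_normalized_across_factors(
        self, small_annotation, small_truth, small_config
    ):
        readsets = {
            f: simulate_chip_reads(small_annotation, small_truth, small_config, f)
            for f in ("POLII", "C-MYC")
        }
        windows = build_tss_windows(small_annotation)
        panel = metaprofile_panel(readsets, windows, small_annotation, bin_size=500)
        assert list(panel.columns) == ["offset", "POLII", "C-MYC"]
        assert len(panel) == 20
        assert (panel[["POLII", "C-MYC"]] >= 0).all().all()
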
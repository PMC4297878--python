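"""End-to-end orchestration: simulate → promoter occupancy → targets →
overlap → amplification, with a flat key=value config, input validation,
and a machine-readable JSON run report.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .amplification import cdf_shift_test, fold_summary, mad_normalize, rpkm
from .expression import ExpressionMatrix
from .genome import FACTORS, GenomeAnnotation, ReadSet, read_chrom_sizes
from .occupancy import (
    call_targets,
    metaprofile_panel,
    build_tss_windows,
    occupancy_table,
    overlap_stats,
    write_target_set,
)
from .simulate import SimulationConfig, write_simulation


@dataclass
class PipelineConfig:
    """Flat run configuration; simulation fields plus analysis thresholds."""

    seed: int = 0
    n_genes: int = 2000
    chrom_size: int = 100_000_000
    chip_enrichment: float = 10.0
    chip_reads_per_factor: int = 200_000
    frag_sd: float = 500.0
    frac_target: float = 0.4
    frac_extra_bound: float = 0.1
    expr_mean_log2: float = 5.0
    expr_sd_log2: float = 1.5
    expr_dispersion: float = 0.05
    amplification_factor: float = 1.5
    n_otosphere: int = 3
    n_imop: int = 2
    flank: int = 5000
    q_threshold: float = 0.05
    min_enrichment: float = 2.0
    rpkm_min: float = 1.0
    rpkm_max: float = 1e4
    cond_a: str = "otosphere"
    cond_b: str = "imop"
    profile_bin_size: int = 100

    def __post_init__(self):
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.min_enrichment < 1:
            raise ValueError("min_enrichment must be >= 1")
        if not (0 < self.rpkm_min < self.rpkm_max):
            raise ValueError("need 0 < rpkm_min < rpkm_max")
        if self.flank <= 0:
            raise ValueError("flank must be positive")

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            chrom_sizes={"chr1": self.chrom_size},
            n_genes=self.n_genes,
            seed=self.seed,
            chip_enrichment=self.chip_enrichment,
            chip_reads_per_factor=self.chip_reads_per_factor,
            frag_sd=self.frag_sd,
            flank=self.flank,
            frac_target=self.frac_target,
            frac_extra_bound=self.frac_extra_bound,
            expr_mean_log2=self.expr_mean_log2,
            expr_sd_log2=self.expr_sd_log2,
            expr_dispersion=self.expr_dispersion,
            amplification_factor=self.amplification_factor,
            n_replicates=(self.n_otosphere, self.n_imop),
        )


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    values: dict[str, object] = {}
    known = {f.name: f.type for f in dc_fields(PipelineConfig)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip().strip("\"'")
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(PipelineConfig, key, None)
            if isinstance(default, bool):
                values[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                values[key] = int(float(val))
            elif isinstance(default, float):
                values[key] = float(val)
            else:
                values[key] = val
    return PipelineConfig(**values)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_full(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order, writing all stage outputs under ``outdir``
    plus ``report.json``. Idempotent (byte-identical outputs) for a fixed
    seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    _log("[simulate] generating synthetic inputs")
    sim = config.simulation_config()
    paths = write_simulation(outdir / "inputs", sim)

    # Reload everything from disk so a run also exercises the readers.
    chrom_sizes = read_chrom_sizes(paths["chrom_sizes"])
    annotation = GenomeAnnotation.read_bed(paths["annotation"], chrom_sizes)
    readsets = {
        f: ReadSet.read_bed(paths[f"reads_{f}"], factor=f) for f in FACTORS
    }
    _log(f"[simulate] done in {time.perf_counter() - t0:.1f}s")

    t1 = time.perf_counter()
    _log("[chip] calling promoter occupancy")
    occ = occupancy_table(
        annotation,
        readsets,
        flank=config.flank,
        q_threshold=config.q_threshold,
        min_enrichment=config.min_enrichment,
    )
    occ.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
    targets = {f: call_targets(occ, f) for f in ("SOX2", "C-MYC")}
    for f, t in targets.items():
        write_target_set(t, outdir / f"targets_{f.replace('-', '')}.txt")
    both = targets["SOX2"] & targets["C-MYC"]
    write_target_set(both, outdir / "targets_both.txt")
    ov = overlap_stats(targets["SOX2"], targets["C-MYC"])
    windows = build_tss_windows(annotation, config.flank)
    profile = metaprofile_panel(
        readsets, windows, annotation, bin_size=config.profile_bin_size
    )
    profile.to_csv(outdir / "tss_metaprofile.tsv", sep="\t", index=False)
    _log(f"[chip] done in {time.perf_counter() - t1:.1f}s")

    t2 = time.perf_counter()
    _log("[amplification] expression analysis")
    counts = ExpressionMatrix.read_tsv(paths["counts"], units="counts")
    expr = rpkm(counts)
    heat = mad_normalize(expr.subset_genes(sorted(both)).values)
    heat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    folds = fold_summary(expr, sorted(both), config.cond_a, config.cond_b)
    shift = cdf_shift_test(
        expr,
        sorted(both),
        config.cond_a,
        config.cond_b,
        rpkm_range=(config.rpkm_min, config.rpkm_max),
    )
    for cond, table in shift.cdf_tables.items():
        table.to_csv(outdir / f"cdf_{cond}.tsv", sep="\t", index=False)
    _log(f"[amplification] done in {time.perf_counter() - t2:.1f}s")

    report = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "targets": {
            "SOX2": len(targets["SOX2"]),
            "C-MYC": len(targets["C-MYC"]),
            "both": len(both),
        },
        "overlap": {
            "n_sox2": ov.n_a,
            "n_cmyc": ov.n_b,
            "n_intersection": ov.n_intersection,
            "pct_sox2_also_cmyc": ov.pct_a_in_b,
            "pct_cmyc_also_sox2": ov.pct_b_in_a,
        },
        "fold": {
            "max": folds.max_fold,
            "mean": folds.mean_fold,
            "median": folds.median_fold,
            "n_undefined": folds.n_undefined,
        },
        "shift": {"t": shift.t, "df": shift.df, "p": shift.p,
                  "n_a": shift.n_a, "n_b": shift.n_b},
        "versions": {
            "ampscan": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log(f"[run] complete in {time.perf_counter() - t0:.1f}s")
    return report


# ------------------------------------------------------------- validation


def _validate_bed(path: Path, n_cols: int) -> list[dict]:
    diags = []
    prev: tuple[str, int] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < n_cols:
                diags.append(
                    {"file": str(path), "line": lineno,
                     "message": f"expected >= {n_cols} columns, got {len(parts)}"}
                )
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                diags.append(
                    {"file": str(path), "line": lineno, "message": "non-integer coordinates"}
                )
                continue
            if start >= end:
                diags.append(
                    {"file": str(path), "line": lineno,
                     "message": f"start {start} >= end {end}"}
                )
            if start < 0:
                diags.append(
                    {"file": str(path), "line": lineno, "message": f"negative start {start}"}
                )
            key = (parts[0], start)
            if prev is not None and key < prev:
                diags.append(
                    {"file": str(path), "line": lineno,
                     "message": "not sorted by (chrom, start)"}
                )
            prev = key
    return diags


def _validate_counts(path: Path) -> list[dict]:
    diags = []
    try:
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
    except Exception as exc:  # noqa: BLE001 - reported as a diagnostic
        return [{"file": str(path), "line": 0, "message": f"unparseable counts table: {exc}"}]
    if "length" not in df.columns:
        diags.append({"file": str(path), "line": 1, "message": "missing 'length' column"})
        return diags
    counts = df.drop(columns="length")
    for sample in counts.columns:
        col = counts[sample]
        bad_neg = col[col < 0]
        for gene in bad_neg.index[:10]:
            diags.append(
                {"file": str(path), "line": 0,
                 "message": f"negative count for gene {gene}, sample {sample}"}
            )
        nonint = col[(col % 1) != 0]
        for gene in nonint.index[:10]:
            diags.append(
                {"file": str(path), "line": 0,
                 "message": f"non-integer count for gene {gene}, sample {sample}"}
            )
    return diags


def _validate_fasta(path: Path) -> list[dict]:
    diags = []
    allowed = set("ACGTNacgtn")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(">"):
                continue
            bad = set(line) - allowed
            if bad:
                diags.append(
                    {"file": str(path), "line": lineno,
                     "message": f"non-ACGTN characters {sorted(bad)}"}
                )
    return diags


def validate_inputs(paths: Mapping[str, str | Path]) -> list[dict]:
    """Validate input files by kind without mutating them.

    ``paths`` maps a kind — ``annotation`` (BED6), ``reads*`` (BED3),
    ``counts`` (TSV), ``fasta``/``bisulfite*`` (FASTA) — to a file path.
    Returns machine-readable diagnostics (empty list = all clean).
    """
    diags: list[dict] = []
    for kind, p in paths.items():
        p = Path(p)
        if not p.exists():
            diags.append({"file": str(p), "line": 0, "message": "file not found"})
            continue
        if kind.startswith("annotation"):
            diags.extend(_validate_bed(p, 6))
        elif kind.startswith("reads"):
            diags.extend(_validate_bed(p, 3))
        elif kind.startswith("counts"):
            diags.extend(_validate_counts(p))
        elif kind.startswith(("fasta", "bisulfite")):
            diags.extend(_validate_fasta(p))
        else:
            diags.append({"file": str(p), "line": 0, "message": f"unknown input kind {kind!r}"})
    return diags
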
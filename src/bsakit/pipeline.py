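"""End-to-end orchestration: simulate -> filter -> scan -> call -> CNV -> expression.

One :class:`RunConfig` (YAML-loadable) drives every stage with a single
global seed fanned out per stage, so a rerun with the same config is
bit-identical. The run writes all stage artifacts (VCF, LOD TSVs, QTL and
common-region BEDs, coverage bedGraph, aneuploidy TSV, expression tables)
plus a phenotype-cluster bookkeeping report and a manifest with SHA-256
checksums of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bsa import compare_all_pools, intervals_to_frame
from .cnv import call_aneuploidy, chromosome_ratios
from .expression import bin_fold_changes, chromosome_dosage_summary, log2_fold_change
from .genome import GenomeSpec
from .simulate import (
    INTERMEDIATE,
    RESISTANT_EVOLVED,
    RESISTANT_PARENTAL,
    SENSITIVE,
    CrossConfig,
    DepthModel,
    assign_phenotypes,
    simulate_coverage,
    simulate_expression,
    simulate_meiosis,
    simulate_parent_counts,
    simulate_parent_sites,
    simulate_pool_reads,
    write_bedgraph,
    write_expression_tsv,
    write_truth,
)
from .variant_io import call_het_sites, read_vcf, write_bed, write_vcf

__all__ = ["RunConfig", "ClusterReport", "cluster_report", "run_pipeline"]

logger = logging.getLogger(__name__)

POOLED_CLASSES = (SENSITIVE, RESISTANT_PARENTAL, RESISTANT_EVOLVED)


@dataclass
class RunConfig:
    """Parameters for a full simulated run; loadable from YAML."""

    outdir: str = "bsakit_run"
    seed: int = 1

    # cross simulation
    n_sites: int = 2000
    n_segregants: int = 69
    qtl_major: tuple[str, int] = ("chrXII", 543_500)
    qtl_minor: tuple[str, int] = ("chrIV", 471_500)
    intermediate_fraction: float = 0.4

    # sequencing
    pool_depth: float = 80.0
    parent_depth: float = 133.0
    error_rate: float = 0.002

    # marker filter / scan
    af_min: float = 0.25
    af_max: float = 0.75
    min_depth: int = 20
    lod_threshold: float = 3.0
    lod_drop: float = 1.0

    # coverage / CNV
    copy_numbers: dict = field(default_factory=lambda: {"chrI": 3})
    coverage_depth: float = 100.0
    window: int = 1000
    baseline_ploidy: int = 2
    cnv_tolerance: float = 0.15

    # expression
    n_genes: int = 5000
    dosage: dict = field(default_factory=lambda: {"chrI": 1.5})
    dispersion: float = 0.05
    n_reps: tuple[int, int] = (3, 1)
    exclude_chromosomes: tuple[str, ...] = ("chrI",)

    plots: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.af_min <= self.af_max <= 1:
            raise ValueError("require 0 <= af_min <= af_max <= 1")
        if self.min_depth < 0 or self.lod_threshold < 0 or self.lod_drop <= 0:
            raise ValueError("invalid scan thresholds")
        if self.window < 100 or self.baseline_ploidy < 1:
            raise ValueError("invalid coverage parameters")
        self.qtl_major = tuple(self.qtl_major)  # type: ignore[assignment]
        self.qtl_minor = tuple(self.qtl_minor)  # type: ignore[assignment]
        self.n_reps = tuple(self.n_reps)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qtl_major"] = list(self.qtl_major)
        d["qtl_minor"] = list(self.qtl_minor)
        d["n_reps"] = list(self.n_reps)
        d["exclude_chromosomes"] = list(self.exclude_chromosomes)
        return d


@dataclass(frozen=True)
class ClusterReport:
    """Phenotype-class bookkeeping: counts and nearest-integer percentages."""

    counts: dict[str, int]
    percentages: dict[str, int]
    total: int


def cluster_report(labels) -> ClusterReport:
    """Tabulate phenotype labels into counts and rounded percentages."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to report")
    counts = dict(pd.Series(labels).value_counts().sort_index())
    counts = {str(k): int(v) for k, v in counts.items()}
    total = len(labels)
    percentages = {k: round(100 * v / total) for k, v in counts.items()}
    return ClusterReport(counts=counts, percentages=percentages, total=total)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = GenomeSpec()
    outputs: dict[str, Path] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)

    # --- simulate cross -----------------------------------------------------
    _stage("simulate_cross")
    sites = simulate_parent_sites(config.n_sites, genome, seed=config.seed)
    cross = CrossConfig(
        n_segregants=config.n_segregants,
        qtl_major=config.qtl_major,
        qtl_minor=config.qtl_minor,
        intermediate_fraction=config.intermediate_fraction,
        seed=config.seed,
    )
    segregants = assign_phenotypes(simulate_meiosis(sites, cross, genome), cross)

    report = cluster_report(segregants.phenotypes)
    outputs["cluster_report"] = outdir / "cluster_report.json"
    outputs["cluster_report"].write_text(json.dumps(dataclasses.asdict(report), indent=2) + "\n")

    # --- pooled sequencing + VCF -------------------------------------------
    _stage("pooled_sequencing")
    sample_counts = {
        "parent": simulate_parent_counts(
            sites, DepthModel(config.parent_depth, config.error_rate, seed=config.seed)
        )
    }
    depth = DepthModel(config.pool_depth, config.error_rate, seed=config.seed)
    for label in POOLED_CLASSES:
        if len(segregants.pool_members(label)) == 0:
            raise RuntimeError(f"simulated cross produced an empty {label} pool; change the seed")
        sample_counts[label] = simulate_pool_reads(segregants, label, depth)
    outputs["vcf"] = outdir / "cross.vcf"
    write_vcf(outputs["vcf"], sites, sample_counts, genome)

    # --- marker filter ------------------------------------------------------
    _stage("filter_het_sites")
    records = read_vcf(outputs["vcf"], required_samples=["parent", *POOLED_CLASSES])
    het = call_het_sites(
        records, "parent", af_min=config.af_min, af_max=config.af_max, min_depth=config.min_depth
    )
    outputs["het_sites"] = outdir / "het_sites.tsv"
    het.to_csv(outputs["het_sites"], sep="\t", index=False)

    # --- LOD scan + QTL calls ----------------------------------------------
    _stage("bsa_scan")
    pools = {
        label: het[["chrom", "pos"]].assign(
            ref_depth=het[f"{label}.ref_depth"], alt_depth=het[f"{label}.alt_depth"]
        )
        for label in POOLED_CLASSES
    }
    for label, df in pools.items():
        df.attrs["pool"] = label
    result = compare_all_pools(
        het, pools, threshold=config.lod_threshold, drop=config.lod_drop
    )
    all_intervals = []
    for key, track in result["tracks"].items():
        tag = key.replace("|", "_vs_")
        p = outdir / f"lod_{tag}.tsv"
        track.to_csv(p, sep="\t", index=False, float_format="%.4f")
        outputs[f"lod_{tag}"] = p
        all_intervals.extend(result["intervals"][key])
        if config.plots:
            from .plots import plot_lod_track

            plot_lod_track(track, outdir / f"lod_{tag}.png", threshold=config.lod_threshold)
    outputs["qtl_bed"] = outdir / "qtl_intervals.bed"
    write_bed(intervals_to_frame(all_intervals), outputs["qtl_bed"])
    outputs["common_bed"] = outdir / "common_region.bed"
    write_bed(result["common"].assign(name="common"), outputs["common_bed"])

    # --- coverage + aneuploidy ----------------------------------------------
    _stage("cnv_scan")
    windows = simulate_coverage(
        genome,
        copy_numbers=config.copy_numbers,
        window=config.window,
        mean_depth=config.coverage_depth,
        seed=config.seed,
        baseline_ploidy=config.baseline_ploidy,
    )
    outputs["coverage_bedgraph"] = outdir / "coverage.bedgraph"
    write_bedgraph(windows, outputs["coverage_bedgraph"])
    ratios = chromosome_ratios(windows)
    calls = call_aneuploidy(
        ratios, baseline_ploidy=config.baseline_ploidy, tolerance=config.cnv_tolerance
    )
    outputs["aneuploidy"] = outdir / "aneuploidy.tsv"
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        outputs["aneuploidy"], sep="\t", index=False, float_format="%.4f"
    )
    if config.plots:
        from .plots import plot_coverage

        plot_coverage(windows, outdir / "coverage.png")

    # --- expression dosage --------------------------------------------------
    _stage("expression_dosage")
    counts, annotation = simulate_expression(
        n_genes=config.n_genes,
        dosage=config.dosage,
        n_reps=config.n_reps,
        dispersion=config.dispersion,
        seed=config.seed,
        genome=genome,
    )
    outputs["expression_counts"] = outdir / "expression_counts.tsv"
    write_expression_tsv(counts, annotation, outputs["expression_counts"])
    parent_samples = [c for c in counts.columns if c.startswith("parent_")]
    evolved_samples = [c for c in counts.columns if c.startswith("evolved_")]
    fc = log2_fold_change(counts, parent_samples, evolved_samples)
    outputs["log2_fc"] = outdir / "log2_fold_change.tsv"
    fc.to_frame().join(annotation).to_csv(outputs["log2_fc"], sep="\t", float_format="%.4f")
    summary = chromosome_dosage_summary(fc, annotation["chrom"])
    outputs["dosage_summary"] = outdir / "dosage_summary.tsv"
    summary.to_csv(outputs["dosage_summary"], sep="\t", float_format="%.4f")
    bins = bin_fold_changes(
        fc,
        chromosomes=annotation["chrom"],
        exclude_chromosomes=tuple(config.exclude_chromosomes),
    )
    outputs["fc_bins"] = outdir / "fc_bins.tsv"
    bins.to_frame("n_genes").to_csv(outputs["fc_bins"], sep="\t")

    # --- truth + manifest ----------------------------------------------------
    outputs["truth"] = outdir / "truth.json"
    write_truth(
        outputs["truth"],
        qtl_major=list(config.qtl_major),
        qtl_minor=list(config.qtl_minor),
        copy_numbers=config.copy_numbers,
        dosage=config.dosage,
        seed=config.seed,
    )
    manifest = {
        "bsakit_version": __version__,
        "parameters": config.to_dict(),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
        },
        "cluster_report": dataclasses.asdict(report),
        "n_het_sites": int(len(het)),
        "n_qtl_intervals": len(all_intervals),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
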
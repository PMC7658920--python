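"""End-to-end synthetic pipeline: configuration, staging, provenance.

``run_pipeline`` chains the stages

    simulate -> filter -> count -> score -> detect -> downstream

on a synthetic genome and cohort, writing every intermediate artifact as
a text table with a config-hash/seed header so a run is reproducible
byte-for-byte from its config file.  The ``filter`` stage (read-level
simulation through the end-distance filter) is optional; by default site
counts are drawn directly from the methylation profiles, which is the
same generative model without the read plumbing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counts import SiteCountMatrix
from .dmr import (
    GroupComparison,
    annotate_dmrs,
    filter_dmrs,
    sliding_window_dmrs,
    test_regions,
)
from .downstream import cluster_samples, dmr_group_test, dmr_sample_matrix
from .genome import generate_genome
from .io import (
    config_hash,
    write_bedgraph,
    write_dmr_bed,
    write_dmr_table,
    write_gene_table,
    write_genome_fasta,
    write_intervals_bed,
    write_table,
)
from .reads import assign_reads_to_sites, filter_reads
from .regions import build_regions, score_regions
from .samples import simulate_sample_sheet
from .simulate import (
    digest_genome,
    generate_methylation_profiles,
    plan_injections,
    simulate_reads,
    simulate_site_counts,
    write_fastq,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "filter", "count", "score", "detect", "downstream")


@dataclass
class PipelineConfig:
    """All pipeline constants in one validated, serializable place."""

    seed: int = 0
    # genome
    chrom_lengths: list = field(default_factory=lambda: [60000, 40000])
    cpg_rate: float = 0.05
    n_genes: int = 12
    n_islands: int = 8
    sex_chrom_names: list = field(default_factory=list)
    # cohort
    n_s45f: int = 14
    n_t41a: int = 15
    # injected truth
    n_injected: int = 4
    injected_fold_change: float = 2.0
    injected_n_sites: int = 5
    # methylation / counts
    baseline_mean: float = 0.3
    noise_sd: float = 0.05
    site_sd: float = 0.1
    mean_depth: float = 30.0
    dispersion: float = 0.1
    # read-level simulation (optional path)
    read_level: bool = False
    read_length: int = 50
    offset_jitter: list = field(default_factory=lambda: [13, 17])
    # filter
    filter_window: list = field(default_factory=lambda: [13, 17])
    # regions
    tss_flank: int = 1000
    # detection
    alpha: float = 0.05
    site_alpha: float = 0.05
    correction_method: str = "bh"
    correction_family: str = "sites"
    min_sites: int = 2
    max_gap: int = 1000
    pseudocount: float = 0.5
    fc_threshold: float = 1.5
    exclude_sex: bool = True
    # clustering
    linkage: str = "average"
    metric: str = "euclidean"
    normalization: str = "cpm"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 < self.alpha < 1 or not 0 < self.site_alpha < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.max_gap < 0 or self.tss_flank < 0:
            raise ValueError("max_gap and tss_flank must be non-negative")
        lo, hi = self.filter_window
        if not 0 <= lo <= hi:
            raise ValueError(f"invalid filter window {self.filter_window}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        return config_hash(asdict(self))


def run_pipeline(
    config: PipelineConfig,
    outdir,
    stages: "tuple | list" = STAGES,
) -> dict:
    """Run a prefix of the stage list; returns the machine-readable report.

    Stage outputs land in ``outdir``; the report records per-stage record
    counts, the configuration, its hash, and library versions.  Re-running
    with the same config reproduces every artifact byte-identically.
    """
    stages = tuple(stages)
    if stages != STAGES[: len(stages)]:
        raise ValueError(f"stages must be a prefix of {STAGES}, got {stages}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed,
            "normalization": config.normalization}
    report: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "stages": {},
        "versions": _versions(),
    }
    config.to_yaml(outdir / "config.yaml")

    # --- simulate ----------------------------------------------------------
    genome = generate_genome(
        config.chrom_lengths,
        cpg_rate=config.cpg_rate,
        n_genes=config.n_genes,
        n_islands=config.n_islands,
        sex_chrom_names=config.sex_chrom_names,
        seed=config.seed,
    )
    sheet = simulate_sample_sheet(config.n_s45f, config.n_t41a, seed=config.seed + 1)
    injected = plan_injections(
        genome,
        config.n_injected,
        fold_change=config.injected_fold_change,
        n_sites=config.injected_n_sites,
        seed=config.seed + 2,
    )
    profile, injected = generate_methylation_profiles(
        genome, sheet, injected,
        baseline_mean=config.baseline_mean,
        noise_sd=config.noise_sd,
        site_sd=config.site_sd,
        seed=config.seed + 3,
    )
    sites = genome.lpnpi_sites()
    write_genome_fasta(genome, outdir / "genome.fa")
    write_gene_table(genome.genes, outdir / "genes.tsv", meta)
    write_intervals_bed(genome.cpg_islands, outdir / "cpg_islands.bed")
    write_intervals_bed(
        [(c, p, p + 2) for c, p in sites.itertuples(index=False)],
        outdir / "lpnpi_sites.bed",
    )
    write_table(sheet, outdir / "sample_sheet.tsv", meta)
    truth_frame = pd.DataFrame(
        [
            {"chrom": t.chrom, "start": t.start, "end": t.end,
             "fold_change": t.fold_change, "hyper_group": t.hyper_group,
             "n_sites": len(t.site_positions)}
            for t in injected
        ]
    )
    write_table(truth_frame, outdir / "injected_truth.tsv", meta)
    report["stages"]["simulate"] = {
        "n_chromosomes": len(genome.chromosomes),
        "n_sites": len(sites),
        "n_genes": len(genome.genes),
        "n_islands": len(genome.cpg_islands),
        "n_samples": len(sheet),
        "n_injected": len(injected),
    }
    if len(stages) == 1:
        return _finish(report, outdir)

    # --- filter / count ----------------------------------------------------
    if config.read_level:
        all_kept = []
        n_reads = n_kept = 0
        for si, sample in enumerate(profile.samples):
            frags = digest_genome(genome, profile, sample, seed=config.seed + 100 + si)
            records, truth = simulate_reads(
                frags, genome,
                read_length=config.read_length,
                offset_jitter=tuple(config.offset_jitter),
                seed=config.seed + 200 + si,
            )
            write_fastq(records, outdir / f"reads_{sample}.fastq")
            reads = truth.rename(columns={"offset": "site_offset"})
            reads["length"] = config.read_length
            reads["sample"] = sample
            kept, rep = filter_reads(
                reads[["read_id", "chrom", "start", "length", "sample"]],
                offsets=[
                    [o] for o in truth["offset"].tolist()
                ],
                window=tuple(config.filter_window),
            )
            n_reads += rep.n_input
            n_kept += rep.n_kept
            all_kept.append(kept)
        kept_all = (
            pd.concat(all_kept, ignore_index=True)
            if all_kept
            else pd.DataFrame(columns=["read_id", "chrom", "start", "length",
                                       "sample", "site_offset", "site_pos"])
        )
        matrix, unassigned = assign_reads_to_sites(kept_all, sites, profile.samples)
        report["stages"]["filter"] = {
            "n_reads": n_reads, "n_kept": n_kept,
            "n_discarded": n_reads - n_kept, "n_unassigned": unassigned,
        }
    else:
        matrix = simulate_site_counts(
            profile,
            mean_depth=config.mean_depth,
            dispersion=config.dispersion,
            seed=config.seed + 4,
        )
        report["stages"]["filter"] = {"skipped": "count shortcut (read_level=false)"}
    if len(stages) == 2:
        return _finish(report, outdir)

    counts_out = matrix.sites()
    counts_out = pd.concat(
        [counts_out, matrix.counts.reset_index(drop=True)], axis=1
    )
    write_table(counts_out, outdir / "site_counts.tsv", meta)
    report["stages"]["count"] = {
        "n_sites": matrix.n_sites,
        "library_sizes": {s: int(v) for s, v in matrix.library_sizes.items()},
    }
    if len(stages) == 3:
        return _finish(report, outdir)

    # --- score -------------------------------------------------------------
    regions = build_regions(
        genome.genes, genome.cpg_islands, genome.chrom_lengths(),
        tss_flank=config.tss_flank,
    )
    region_matrix = score_regions(matrix, regions)
    region_out = pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "class": [r.region_class for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_sites": region_matrix.n_sites.to_numpy(),
        }
    )
    region_out = pd.concat(
        [region_out, region_matrix.counts.reset_index(drop=True)], axis=1
    )
    write_table(region_out, outdir / "region_scores.tsv", meta)
    report["stages"]["score"] = {"n_regions": len(regions)}
    if len(stages) == 4:
        return _finish(report, outdir)

    # --- detect ------------------------------------------------------------
    groups = GroupComparison.from_sample_sheet(sheet)
    window_dmrs = sliding_window_dmrs(
        matrix, groups,
        site_alpha=config.site_alpha,
        min_sites=config.min_sites,
        max_gap=config.max_gap,
        alpha=config.alpha,
        method=config.correction_method,
        correction_family=config.correction_family,
        pseudocount=config.pseudocount,
    )
    window_dmrs = annotate_dmrs(window_dmrs, regions)
    kept_dmrs = filter_dmrs(
        window_dmrs, fc_threshold=config.fc_threshold, exclude_sex=config.exclude_sex
    )
    region_dmrs = test_regions(
        region_matrix, groups,
        alpha=config.alpha,
        method=config.correction_method,
        pseudocount=config.pseudocount,
    )
    write_dmr_table(window_dmrs, outdir / "dmrs_window.tsv", meta)
    write_dmr_table(kept_dmrs, outdir / "dmrs_window_filtered.tsv", meta)
    write_dmr_table(region_dmrs, outdir / "dmrs_regions.tsv", meta)
    write_dmr_bed(window_dmrs, outdir / "dmrs_window.bed")
    # per-site p-value track for browser loading
    from .dmr import _chi2_vec, _group_totals  # noqa: PLC0415

    a, b, lib_a, lib_b = _group_totals(matrix.counts, matrix.library_sizes, groups)
    _, p_site = _chi2_vec(a, lib_a - a, b, lib_b - b)
    write_bedgraph(
        pd.Series(p_site, index=matrix.counts.index),
        outdir / "site_pvalues.bedgraph",
        track_name="site_p",
    )
    report["stages"]["detect"] = {
        "n_window_dmrs": len(window_dmrs),
        "n_window_dmrs_filtered": len(kept_dmrs),
        "n_region_dmrs": len(region_dmrs),
    }
    if len(stages) == 5:
        return _finish(report, outdir)

    # --- downstream --------------------------------------------------------
    norm = matrix.normalized()
    down: dict = {"n_dmrs_tested": 0}
    if window_dmrs:
        mwu = dmr_group_test(window_dmrs, norm, groups)
        write_table(mwu, outdir / "dmr_mannwhitney.tsv", meta)
        heat = dmr_sample_matrix(window_dmrs, norm)
        if len(heat) and heat.shape[1] >= 2:
            clust = cluster_samples(
                heat, sheet, linkage=config.linkage, metric=config.metric
            )
            (outdir / "cluster_tree.nwk").write_text(clust.to_newick() + "\n")
            write_table(
                clust.matrix.loc[:, clust.order].reset_index(names="dmr"),
                outdir / "heatmap_matrix.tsv",
                meta,
            )
            write_table(clust.purity, outdir / "cluster_purity.tsv", meta)
            down["cluster_order"] = clust.order
        down["n_dmrs_tested"] = len(mwu)
    report["stages"]["downstream"] = down
    return _finish(report, outdir)


def _versions() -> dict:
    import numpy
    import scipy

    return {
        "medseqdmr": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _finish(report: dict, outdir: Path) -> dict:
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
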
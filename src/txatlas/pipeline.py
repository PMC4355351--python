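"""End-to-end orchestration: simulate inputs, run every stage, write outputs.

``run_all`` executes io -> TAR classification -> expression profiles ->
splicing -> chromosome partition -> co-expression, writing TSV/BED/JSON
outputs and a machine-readable ``summary.json``. Every threshold the stages
use lives in :class:`RunConfig`; nothing is hard-coded in stage logic.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import (
    chromosome_partition as cp,
    coexpression_clusters as cc,
    expression_profiles as ep,
    io_formats as iof,
    splicing_events as se,
    synthetic_data as sd,
    tar_classification as tc,
)
from .models import CATEGORY_PSEUDO, RegionTable

log = logging.getLogger("txatlas.pipeline")


@dataclass
class RunConfig:
    """Paths, thresholds, and the region table for a pipeline run."""

    gff3: str = ""
    fpkm: str = ""
    fasta: Optional[str] = None
    antisense: Optional[str] = None
    ntr_bed: Optional[str] = None
    similarity: Optional[str] = None
    term_map: Optional[str] = None
    outdir: str = "results/run"

    fpkm_floor: float = 0.0
    lincrna_min_length_nt: int = 200
    lincrna_max_orf_aa: int = 300
    cis_nat_min_overlap_bp: int = 1
    insula_gap_bp: int = 30_000
    cluster_cut_similarity: float = 0.641
    window_bp: int = 10_000_000
    step_bp: int = 1_000_000
    n_expression_bins: int = 30
    level_cuts: tuple = (5.0, 200.0)
    chrom_length: Optional[int] = None
    regions: Optional[list] = None  # [[name, start_bp, end_bp], ...]
    seed: int = 0

    def validate(self) -> None:
        for name in ("fpkm_floor",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "lincrna_min_length_nt", "lincrna_max_orf_aa", "cis_nat_min_overlap_bp",
            "insula_gap_bp", "window_bp", "step_bp", "n_expression_bins",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for path in (self.gff3, self.fpkm):
            if path and not Path(path).exists():
                raise ValueError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: Optional[dict] = None) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides or {})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def region_table(self, chrom_length: int) -> RegionTable:
        if self.regions:
            rt = RegionTable([(str(n), int(s), int(e)) for n, s, e in self.regions])
        else:
            scale = chrom_length / (sd.FULL_SCALE_REGIONS_MB[-1][2] * 1e6)
            rt = RegionTable(
                [
                    (n, int(round(a * 1e6 * scale)), int(round(b * 1e6 * scale)))
                    for n, a, b in sd.FULL_SCALE_REGIONS_MB
                ]
            )
        rt.validate()
        return rt


def _read_ntr_bed(path: str | Path) -> dict[str, tuple[int, int]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            out[fields[3]] = (int(fields[1]) + 1, int(fields[2]))
    return out


def _read_similarity(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["tar_id"], df["has_protein_similarity"].astype(bool)))


def _stage(name: str, t0: float, n_in: int, n_out: int) -> None:
    log.info("stage=%s in=%d out=%d elapsed=%.2fs", name, n_in, n_out, time.time() - t0)


def simulate(config: sd.SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic input bundle readable by :func:`run_all`."""
    ds = sd.generate_chromosome(config)
    return sd.write_dataset(ds, outdir)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    # --- io ----------------------------------------------------------------
    t0 = time.time()
    genes = iof.read_gff3(config.gff3)
    matrix = iof.read_expression_matrix(config.fpkm)
    ntr_intervals = _read_ntr_bed(config.ntr_bed) if config.ntr_bed else {}
    sequences = iof.read_fasta(config.fasta) if config.fasta else None
    similarity = _read_similarity(config.similarity) if config.similarity else {}
    antisense = iof.read_antisense_table(config.antisense) if config.antisense else None
    chrom_length = config.chrom_length or max(g.end for g in genes)
    regions = config.region_table(chrom_length)
    _stage("io", t0, 0, len(genes))

    # --- TAR classification --------------------------------------------------
    t0 = time.time()
    tars = tc.call_tars(genes, matrix, ntr_intervals, fpkm_floor=config.fpkm_floor)
    expressed_ids = {t.tar_id for t in tars}
    ntr_tars = [t for t in tars if t.tar_class == "NTR"]

    if sequences is not None:
        linc_calls = tc.classify_lincRNAs(
            ntr_tars, sequences, similarity,
            min_length_nt=config.lincrna_min_length_nt,
            max_orf_aa=config.lincrna_max_orf_aa,
        )
        lincrna_status = "ok"
    else:
        linc_calls = None
        lincrna_status = "uncallable: no FASTA provided"
        log.warning("lincRNA stage skipped: no transcript sequences")

    nat_calls = None
    if antisense is not None and len(antisense):
        nat_calls = tc.detect_cis_nats(
            genes, antisense, expressed_ids, min_overlap_bp=config.cis_nat_min_overlap_bp
        )
    tar_summary = tc.summarize_tars(
        tars, genes, chrom_length_bp=chrom_length,
        lincrna_calls=linc_calls, similarity_flags=similarity,
        cis_nat_calls=nat_calls,
    )
    tar_summary["lincrna_status"] = lincrna_status
    tc.tars_to_table(tars).to_csv(outdir / "tars.tsv", sep="\t", index=False)
    iof.write_bed(
        [(t.chrom, t.start, t.end, t.tar_id, ".", t.strand) for t in tars],
        outdir / "tars.bed",
    )
    _stage("tar_classification", t0, len(matrix.loci), len(tars))

    # --- expression profiles -------------------------------------------------
    t0 = time.time()
    profiles = ep.profile_expression(matrix)
    expressed_genes = [g for g in genes if g.gene_id in expressed_ids]
    structures = ep.gene_structure_table(genes)
    gene_profiles = [p for p in profiles if p.locus_id in structures.index]
    bins = None
    if sum(p.expressed for p in gene_profiles) >= config.n_expression_bins:
        bins = ep.bin_by_expression(gene_profiles, structures, config.n_expression_bins)
        bins.to_csv(outdir / "expression_bins.tsv", sep="\t", index=False)
        inflexion, monotone = ep.detect_inflexion(bins, "transcript_length")
        summary["inflexion_bin_transcript_length"] = inflexion
        summary["inflexion_monotone"] = bool(monotone)
    prof_df = pd.DataFrame(
        {
            "locus": [p.locus_id for p in profiles],
            "breadth": [p.breadth for p in profiles],
            "mean_expr": [p.mean_expr for p in profiles],
            "level_class": [p.level_class for p in profiles],
            "organ_specific": [p.organ_specific for p in profiles],
        }
    )
    prof_df.to_csv(outdir / "expression_profiles.tsv", sep="\t", index=False)
    expressed_gene_profiles = [p for p in gene_profiles if p.expressed]
    summary["mean_breadth"] = round(
        float(np.mean([p.breadth for p in expressed_gene_profiles])), 1
    ) if expressed_gene_profiles else None
    _stage("expression_profiles", t0, len(matrix.loci), len(profiles))

    # --- splicing -------------------------------------------------------------
    t0 = time.time()
    events = []
    for g in expressed_genes:
        events.extend(se.classify_as_events(g))
    as_sum = se.as_summary(expressed_genes, events)
    se.events_to_table(events).to_csv(outdir / "as_events.tsv", sep="\t", index=False)
    _stage("splicing_events", t0, len(expressed_genes), len(events))

    # --- chromosome partition --------------------------------------------------
    t0 = time.time()
    mids = [g.midpoint for g in genes]
    expr_mids = [g.midpoint for g in expressed_genes]
    track = cp.windowed_density(
        expr_mids, chrom_length, window=config.window_bp, step=config.step_bp,
        chrom=genes[0].chrom if genes else ".",
    )
    track = cp.zscore(track)
    # changepoints are found on a non-overlapping track: sliding windows
    # share data, which deflates the first-difference noise estimate and
    # makes binary segmentation oversegment
    tiled = cp.windowed_density(
        expr_mids, chrom_length, window=config.window_bp, step=config.window_bp,
        chrom=genes[0].chrom if genes else ".",
    )
    seg = cp.binary_segmentation(tiled.values, step_bp=config.window_bp)
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.starts,
            "end": track.starts + track.window,
            "density_per_mb": track.values,
            "zscore": track.zscores,
        }
    ).to_csv(outdir / "density_track.tsv", sep="\t", index=False)
    dens = cp.region_density(expr_mids, regions)
    dens.to_csv(outdir / "region_density.tsv", sep="\t", index=False)
    dist = cp.distance_to_centromere(track.starts + track.window / 2, regions)
    rho, pval = cp.spearman_gradient(track.values, -dist)
    summary["density_vs_centromere_distance_spearman"] = round(float(-rho), 3)
    summary["segmentation_changepoints_bp"] = seg.changepoint_bp
    summary["region_density_per_mb"] = dict(
        zip(dens["region"], dens["density_per_mb"].round(2))
    )
    _stage("chromosome_partition", t0, len(mids), len(seg.changepoints))

    # --- co-expression -----------------------------------------------------------
    t0 = time.time()
    expressed_gene_ids = sorted(
        g.gene_id for g in expressed_genes
    )
    cluster_input = matrix.values.loc[expressed_gene_ids]
    assignment = cc.cluster_profiles(cluster_input, config.cluster_cut_similarity)
    insulae = cc.detect_insulae(expressed_genes, gap_threshold=config.insula_gap_bp)
    pairs, pair_summary = cc.coexpressed_pairs(
        insulae, assignment.assignments, expressed_genes
    )
    ins_sum = cc.insulae_summary(insulae, len(expressed_genes))
    positions = {g.gene_id: g.midpoint for g in expressed_genes}
    composition, comp_tests = cc.cluster_region_composition(
        assignment.assignments, positions, regions
    )
    pd.DataFrame(
        sorted(assignment.assignments.items()), columns=["gene", "cluster"]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    comp_tests.to_csv(outdir / "cluster_region_tests.tsv", sep="\t", index=False)
    summary["n_expression_clusters"] = assignment.n_clusters
    summary.update({f"insulae_{k}": v for k, v in ins_sum.items()})
    summary.update({f"pairs_{k}": v for k, v in pair_summary.items()})
    _stage("coexpression", t0, len(expressed_gene_ids), assignment.n_clusters)

    summary["tar_summary"] = tar_summary
    summary["as_summary"] = as_sum
    summary["seed"] = config.seed
    summary.pop("stages")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
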
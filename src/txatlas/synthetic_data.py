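"""Synthetic chromosome generator.

Emulates the statistical structure a chromosome-scale transcriptome map
assumes: five regions with a centromere-to-telomere gene-density gradient,
pseudogene and novel-transcribed-region (NTR) loci, multi-isoform genes whose
extra isoforms are produced by injecting alternative-splicing events at
configured type proportions, an FPKM matrix over 15 organ:stage conditions
with template-based cluster structure, a bell-shaped coupling between
expression level and gene structure, gene islands with a ~30 kb gap scale,
and stranded antisense transcription for a configured fraction of genes.

Every emitted locus and event carries a truth record so downstream stages can
be tested by exact recovery. Output is deterministic for a fixed seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .models import (
    CATEGORY_FULL,
    CATEGORY_PSEUDO,
    Condition,
    ExpressionMatrix,
    GeneModel,
    RegionTable,
    TranscriptModel,
)

# Canonical full-scale region boundaries (Mb) of the reference chromosome.
FULL_SCALE_REGIONS_MB = [
    ("R1", 0.0, 68.0),
    ("R2a", 68.0, 265.0),
    ("C", 265.0, 387.0),
    ("R2b", 387.0, 715.0),
    ("R3", 715.0, 774.4),
]

ORGANS = ("leaf", "shoot", "root", "spike", "grain")
STAGES = ("1", "2", "3")

AS_TYPE_PROPORTIONS = {"IR": 0.35, "A3SS": 0.27, "ES": 0.21, "A5SS": 0.16, "MXE": 0.009}


@dataclass
class SyntheticConfig:
    """Generator parameters. Defaults emulate the full-scale study chromosome;
    use :meth:`test_scale` for a fast ~50 Mb / ~500 gene configuration."""

    chrom: str = "chrSim"
    scale: float = 1.0  # linear scaling applied to the canonical 774.4 Mb map
    # predicted-gene densities per region, genes/Mb (gradient: telomeres high,
    # centromeric core ~1-2)
    gene_density: dict = field(
        default_factory=lambda: {"R1": 18.0, "R2a": 10.5, "C": 1.8, "R2b": 9.2, "R3": 16.0}
    )
    pseudogene_fraction: float = 0.267  # 1,938 / 7,264
    expressed_prob_full: float = 0.774  # 4,125 / 5,326
    expressed_prob_pseudo: float = 0.547  # 1,060 / 1,938
    syntenic_prob: float = 0.6
    ntr_per_gene: float = 0.5  # 3,692 NTRs vs 7,264 predicted genes
    ntr_protein_similar_fraction: float = 0.28  # 1,033 / 3,692
    ntr_lincrna_fraction_of_nonsimilar: float = 0.224  # 596 / 2,659
    cis_nat_fraction: float = 0.122
    as_type_proportions: dict = field(default_factory=lambda: dict(AS_TYPE_PROPORTIONS))
    p_multi_isoform: float = 0.614
    extra_isoform_mean: float = 5.5  # Poisson mean for extra isoforms (slot-capped)
    n_clusters: int = 8
    dropout_rate: float = 0.0  # per-condition dropout, constitutive cluster only
    noise_sigma: float = 0.10  # log-normal multiplicative FPKM noise (log-sd)
    # expression-structure coupling: structure-size factor peaks at this rank
    # fraction of the expression-level distribution (bell shape)
    bell_peak_rank: float = 21.5 / 30.0
    bell_width: float = 0.13
    bell_amplitude: float = 3.0
    size_breadth_coupling: float = -0.5  # log-size slope per breadth/n_conditions
    insula_gap_scale: int = 30_000
    insula_small_gap_weight: float = 0.55
    structure_size_sigma: float = 0.20
    seed: int = 0

    @property
    def regions(self) -> RegionTable:
        rt = RegionTable(
            [
                (name, int(round(a * 1e6 * self.scale)), int(round(b * 1e6 * self.scale)))
                for name, a, b in FULL_SCALE_REGIONS_MB
            ]
        )
        rt.validate()
        return rt

    @property
    def chrom_length(self) -> int:
        return self.regions.length

    @property
    def conditions(self) -> list[Condition]:
        return [
            Condition(f"{o}:{s}", o, s) for o in ORGANS for s in STAGES
        ]

    @classmethod
    def test_scale(cls, seed: int = 0, **kw) -> "SyntheticConfig":
        """~50 Mb chromosome, a few hundred genes; full pipeline in seconds."""
        return cls(scale=50.0 / 774.4, seed=seed, **kw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# AS event injection
# ---------------------------------------------------------------------------


def inject_as_event(
    tx: TranscriptModel,
    event_type: str,
    rng: np.random.Generator,
    tx_id: Optional[str] = None,
    slot: Optional[int] = None,
    strand: str = "+",
) -> tuple[TranscriptModel, tuple]:
    """Return a new isoform differing from ``tx`` by exactly one event.

    ``slot`` is a 0-based intron index; when omitted a feasible one is drawn.
    Returns ``(isoform, truth_coords)`` where truth_coords matches the
    coordinates :func:`txatlas.splicing_events.classify_as_events` reports.
    Raises ValueError when the request is structurally impossible.
    """
    exons = list(tx.exons)
    n = len(exons)
    if event_type == "IR" and n < 2:
        raise ValueError("IR needs >= 2 exons")
    if event_type in ("ES", "MXE") and n < 3:
        raise ValueError(f"{event_type} needs >= 3 exons")
    if event_type in ("A5SS", "A3SS") and n < 2:
        raise ValueError(f"{event_type} needs >= 2 exons")

    def intron(k: int) -> tuple[int, int]:
        return exons[k][1] + 1, exons[k + 1][0] - 1

    def intron_len(k: int) -> int:
        s, e = intron(k)
        return e - s + 1

    candidates = list(range(n - 1)) if slot is None else [slot]
    if event_type in ("ES", "MXE"):
        candidates = [k for k in candidates if k + 1 <= n - 2]
    if event_type in ("A5SS", "A3SS"):
        candidates = [k for k in candidates if intron_len(k) >= 4]
    if event_type == "MXE":
        candidates = [k for k in candidates if intron_len(k + 1) >= 12]
    if not candidates:
        raise ValueError(f"no feasible position for {event_type}")
    k = int(candidates[rng.integers(len(candidates))])

    new_exons = list(exons)
    if event_type == "IR":
        merged = (exons[k][0], exons[k + 1][1])
        new_exons = exons[:k] + [merged] + exons[k + 2 :]
        truth = intron(k)
    elif event_type == "ES":
        skipped = exons[k + 1]
        new_exons = exons[: k + 1] + exons[k + 2 :]
        truth = skipped
    elif event_type in ("A5SS", "A3SS"):
        i_s, i_e = intron(k)
        # donor side of intron k: left exon end on '+', right exon start on '-'
        move_left_exon_end = (event_type == "A5SS") == (strand == "+")
        if move_left_exon_end:
            old = exons[k][1]
            max_shift = min(intron_len(k) - 2, 40)
            delta = int(rng.integers(1, max_shift + 1))
            new_end = old + delta
            new_exons[k] = (exons[k][0], new_end)
            truth = (min(old, new_end) + 1, max(old, new_end))
        else:
            old = exons[k + 1][0]
            max_shift = min(intron_len(k) - 2, 40)
            delta = int(rng.integers(1, max_shift + 1))
            new_start = old - delta
            new_exons[k + 1] = (new_start, exons[k + 1][1])
            truth = (min(old, new_start), max(old, new_start) - 1)
    elif event_type == "MXE":
        # replace exon k+1 by a new exon inside intron k+1
        x = exons[k + 1]
        i_s, i_e = intron(k + 1)
        room = i_e - i_s - 3
        y_len = int(min(max(10, room // 2), 120))
        y_start = i_s + 1
        y = (y_start, y_start + y_len - 1)
        if y[1] >= i_e:
            raise ValueError("intron too small for MXE")
        new_exons = exons[: k + 1] + [y] + exons[k + 2 :]
        truth = tuple(sorted((x, y)))
    else:
        raise ValueError(f"unknown AS type {event_type!r}")

    iso = TranscriptModel(
        tx_id=tx_id or f"{tx.tx_id}.alt", gene_id=tx.gene_id, exons=new_exons
    )
    iso.validate()
    return iso, truth


# ---------------------------------------------------------------------------
# Chromosome generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    matrix: ExpressionMatrix  # gene + NTR loci
    tx_matrix: ExpressionMatrix  # transcript-level rows
    ntr_intervals: dict[str, tuple[int, int]]
    sequences: dict[str, str]  # NTR sequences (FASTA payload)
    antisense: pd.DataFrame
    similarity_flags: dict[str, bool]
    truth: dict


def _bell(u: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    return 1.0 + cfg.bell_amplitude * np.exp(
        -((u - cfg.bell_peak_rank) ** 2) / (2.0 * cfg.bell_width**2)
    )


def _cluster_templates(n_conditions: int = 15) -> list[np.ndarray]:
    """Eight expression templates over 15 conditions (5 organs x 3 stages).

    Template 1 is constitutive (non-flat ramp across all conditions); 2-6 are
    organ-specific; 7 is a late-stage template across organs; 8 is a single
    condition. Supports are chosen with minimal overlap so complete-linkage
    clustering at the configured similarity cut separates them cleanly.
    """
    t = []
    ramp = 0.2 + 1.6 * np.arange(n_conditions) / (n_conditions - 1)
    t.append(ramp / ramp.mean())
    for organ_idx in range(5):
        v = np.zeros(n_conditions)
        sl = slice(3 * organ_idx, 3 * organ_idx + 3)
        v[sl] = [0.7, 1.0, 1.3]
        t.append(v / v[v > 0].mean())
    late = np.zeros(n_conditions)
    late[[2, 5, 8, 11, 14]] = 1.0
    t.append(late)
    single = np.zeros(n_conditions)
    single[7] = 1.0
    t.append(single)
    return t


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _seq_with_long_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(
        np.array(_CODONS)[rng.integers(0, len(_CODONS), size=n_codons - 1)]
    )
    return _random_seq(rng, 9) + "ATG" + body + "TAA" + _random_seq(rng, 9)


def _region_gene_positions(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    n_genes: int,
    spans: list[int],
    cfg: SyntheticConfig,
) -> list[int]:
    """Place ``n_genes`` gene starts with an insula-style gap mixture.

    Gaps are small (<= gap scale) with probability ``insula_small_gap_weight``
    and large otherwise; large gaps are rescaled to fill the region so the
    configured density is met while the small-gap scale is preserved.
    """
    L = region_end - region_start
    total_span = sum(spans)
    if total_span >= 0.8 * L:
        raise ValueError(
            f"region density implies genes exceed region capacity "
            f"({total_span} bp of genes in {L} bp)"
        )
    small = rng.random(n_genes) < cfg.insula_small_gap_weight
    gaps = np.where(
        small,
        rng.integers(200, max(201, cfg.insula_gap_scale - 2000), size=n_genes),
        rng.integers(cfg.insula_gap_scale * 2, cfg.insula_gap_scale * 12, size=n_genes),
    ).astype(float)
    budget = L - total_span - 1
    large_total = gaps[~small].sum()
    small_total = gaps[small].sum()
    if small_total >= budget:  # dense region: shrink everything proportionally
        gaps *= budget / gaps.sum()
    elif large_total > 0:
        factor = (budget - small_total) / large_total
        # keep large gaps above the insula threshold so islands stay distinct
        gaps[~small] = np.maximum(gaps[~small] * factor, cfg.insula_gap_scale * 1.5)
        overshoot = gaps.sum() + total_span - budget
        if overshoot > 0:
            big = gaps[~small]
            gaps[~small] = np.maximum(
                big - overshoot * big / big.sum(), cfg.insula_gap_scale * 1.2
            )
    positions = []
    pos = region_start + 1
    for i in range(n_genes):
        pos += int(gaps[i])
        positions.append(pos)
        pos += spans[i]
    if positions and positions[-1] + spans[-1] > region_end:
        raise ValueError("region density implies more genes than the region can hold")
    return positions


def _build_transcript(
    rng: np.random.Generator,
    gene_id: str,
    start: int,
    n_exons: int,
    exon_lens: np.ndarray,
    intron_lens: np.ndarray,
) -> TranscriptModel:
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i]) - 1))
        pos = exons[-1][1] + 1
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return TranscriptModel(tx_id=f"{gene_id}.1", gene_id=gene_id, exons=exons)


def generate_chromosome(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate annotation, FPKM matrices, sequences, antisense table, truth."""
    rng = np.random.default_rng(cfg.seed)
    regions = cfg.regions
    conditions = cfg.conditions
    n_cond = len(conditions)
    templates = _cluster_templates(n_cond)
    organ_of = {c.cond_id: c.organ for c in conditions}

    genes: list[GeneModel] = []
    truth_loci: dict[str, dict] = {}
    gene_rows: dict[str, np.ndarray] = {}
    tx_rows: dict[str, np.ndarray] = {}
    as_truth: dict[str, list] = {}

    gene_counter = 0
    for name, rstart, rend in regions.regions:
        mb = (rend - rstart) / 1e6
        n_genes = int(round(cfg.gene_density[name] * mb))
        if n_genes == 0:
            continue

        u = rng.random(n_genes)  # latent expression-level rank
        is_pseudo = rng.random(n_genes) < cfg.pseudogene_fraction
        syntenic = rng.random(n_genes) < cfg.syntenic_prob
        expressed = np.where(
            is_pseudo,
            rng.random(n_genes) < cfg.expressed_prob_pseudo,
            rng.random(n_genes) < cfg.expressed_prob_full,
        )

        # cluster assignment: constitutive probability rises with expression
        # level; the centromeric core is enriched in the constitutive cluster
        p_const = np.clip(0.25 + 0.4 * u, 0, 1)
        if name == "C":
            p_const = np.full(n_genes, 0.85)
        p_const = np.where(is_pseudo, p_const * 0.7, p_const)
        other_weights = np.array([0.14, 0.14, 0.14, 0.17, 0.17, 0.13, 0.11])
        cluster = np.empty(n_genes, dtype=int)
        for i in range(n_genes):
            if rng.random() < p_const[i]:
                cluster[i] = 1
            else:
                cluster[i] = 2 + rng.choice(7, p=other_weights / other_weights.sum())

        # breadth support from template, with dropout on the constitutive one
        x_level = 10.0 ** (-0.5 + 4.0 * u)  # FPKM-scale mean expression level

        # structure-size factor: bell over expression rank x breadth coupling
        support_size = np.array([int((templates[c - 1] > 0).sum()) for c in cluster])
        f_size = (
            _bell(u, cfg)
            * np.exp(cfg.size_breadth_coupling * support_size / n_cond)
            * rng.lognormal(0.0, cfg.structure_size_sigma, size=n_genes)
        )
        f_norm = f_size / (1.0 + cfg.bell_amplitude)

        n_exons = 1 + rng.poisson(3.6 * np.sqrt(np.clip(f_norm, 0.02, None)))
        n_exons = np.clip(n_exons, 1, 53)

        spans = []
        gene_structs = []
        for i in range(n_genes):
            ne = int(n_exons[i])
            exon_lens = np.maximum(
                50, (rng.lognormal(np.log(180.0), 0.35, size=ne) * f_size[i] ** 0.5)
            ).astype(int)
            intron_lens = (
                np.maximum(
                    160, rng.lognormal(np.log(380.0), 0.45, size=max(ne - 1, 0)) * f_size[i]
                ).astype(int)
                if ne > 1
                else np.zeros(0, dtype=int)
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            spans.append(span)
            gene_structs.append((ne, exon_lens, intron_lens))

        starts = _region_gene_positions(rng, rstart, rend, n_genes, spans, cfg)

        for i in range(n_genes):
            gene_counter += 1
            gid = f"G{gene_counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            ne, exon_lens, intron_lens = gene_structs[i]
            primary = _build_transcript(rng, gid, starts[i], ne, exon_lens, intron_lens)
            gene = GeneModel(
                gene_id=gid,
                chrom=cfg.chrom,
                start=primary.span[0],
                end=primary.span[1],
                strand=strand,
                category=CATEGORY_PSEUDO if is_pseudo[i] else CATEGORY_FULL,
                syntenic=bool(syntenic[i]),
                transcripts=[primary],
            )

            # extra isoforms via slot-based AS injection (expressed genes only)
            events: list[dict] = []
            if expressed[i] and ne >= 2 and rng.random() < cfg.p_multi_isoform:
                slots = list(range(0, ne - 1, 3))
                n_extra = min(1 + rng.poisson(cfg.extra_isoform_mean), len(slots))
                rng.shuffle(slots)
                type_names = list(cfg.as_type_proportions)
                type_p = np.array([cfg.as_type_proportions[t] for t in type_names])
                type_p = type_p / type_p.sum()
                alt_idx = 0
                for slot in slots[:n_extra]:
                    for _attempt in range(6):
                        etype = type_names[rng.choice(len(type_names), p=type_p)]
                        try:
                            alt_idx += 1
                            iso, coords = inject_as_event(
                                primary,
                                etype,
                                rng,
                                tx_id=f"{gid}.{alt_idx + 1}",
                                slot=slot,
                                strand=strand,
                            )
                        except ValueError:
                            alt_idx -= 1
                            continue
                        gene.transcripts.append(iso)
                        events.append({"type": etype, "coords": coords})
                        break
            gene.validate()

            # expression rows
            if expressed[i]:
                template = templates[cluster[i] - 1].copy()
                vec = x_level[i] * template * rng.lognormal(
                    0.0, cfg.noise_sigma, size=n_cond
                )
                vec[template == 0] = 0.0
                if cluster[i] == 1 and cfg.dropout_rate > 0:
                    drop = rng.random(n_cond) < cfg.dropout_rate
                    vec[drop] = 0.0
                if not (vec > 0).any():
                    vec[int(rng.integers(n_cond))] = x_level[i]
                gene_rows[gid] = vec
                share = rng.dirichlet(np.full(len(gene.transcripts), 2.0))
                for tx, w in zip(gene.transcripts, share):
                    tx_rows[tx.tx_id] = vec * w
            else:
                gene_rows[gid] = np.zeros(n_cond)

            genes.append(gene)
            as_truth[gid] = events
            truth_loci[gid] = {
                "class": "pseudogene" if is_pseudo[i] else "full",
                "region": name,
                "expressed": bool(expressed[i]),
                "cluster": int(cluster[i]) if expressed[i] else None,
                "is_lincRNA": False,
                "is_cis_nat": False,
            }

    genes.sort(key=lambda g: g.start)

    # --- NTR loci in intergenic space -------------------------------------
    n_ntr = int(round(cfg.ntr_per_gene * len(genes)))
    gene_iv = np.array([(g.start, g.end) for g in genes])
    ntr_intervals: dict[str, tuple[int, int]] = {}
    sequences: dict[str, str] = {}
    similarity_flags: dict[str, bool] = {}
    L = cfg.chrom_length
    attempts = 0
    while len(ntr_intervals) < n_ntr and attempts < 50 * n_ntr:
        attempts += 1
        length = int(rng.integers(250, 2500))
        s = int(rng.integers(1, L - length))
        e = s + length - 1
        # reject overlap with genes or existing NTRs
        idx = np.searchsorted(gene_iv[:, 0], e)
        lo = max(0, idx - 8)
        if any(gs <= e and s <= ge for gs, ge in gene_iv[lo : idx + 1]):
            continue
        if any(ns <= e and s <= ne_ for ns, ne_ in ntr_intervals.values()):
            continue
        nid = f"NTR{len(ntr_intervals) + 1:05d}"
        ntr_intervals[nid] = (s, e)

    ntr_ids = sorted(ntr_intervals)
    for nid in ntr_ids:
        similar = rng.random() < cfg.ntr_protein_similar_fraction
        similarity_flags[nid] = bool(similar)
        is_linc = (not similar) and (
            rng.random() < cfg.ntr_lincrna_fraction_of_nonsimilar
        )
        if is_linc:
            seq = _random_seq(rng, int(rng.integers(250, 850)))
        elif rng.random() < 0.5:
            seq = _random_seq(rng, int(rng.integers(60, 200)))  # fails length filter
        else:
            seq = _seq_with_long_orf(rng, 320)  # fails the ORF filter
        sequences[nid] = seq
        template = templates[int(rng.integers(len(templates)))]
        level = 10.0 ** rng.uniform(-0.5, 2.0)
        vec = level * template * rng.lognormal(0.0, cfg.noise_sigma, size=n_cond)
        vec[template == 0] = 0.0
        if not (vec > 0).any():
            vec[int(rng.integers(n_cond))] = level
        gene_rows[nid] = vec
        truth_loci[nid] = {
            "class": "lincRNA" if is_linc else "NTR",
            "region": None,
            "expressed": True,
            "cluster": None,
            "is_lincRNA": is_linc,
            "is_cis_nat": False,
        }

    # --- antisense transcription ------------------------------------------
    anti_rows = []
    expressed_gids = [g.gene_id for g in genes if truth_loci[g.gene_id]["expressed"]]
    n_nat = int(round(cfg.cis_nat_fraction * len(expressed_gids)))
    nat_gids = list(rng.choice(expressed_gids, size=n_nat, replace=False))
    by_id = {g.gene_id: g for g in genes}
    for gid in nat_gids:
        g = by_id[gid]
        span = g.end - g.start + 1
        alen = max(200, int(span * rng.uniform(0.3, 0.9)))
        a_start = g.start + int(rng.integers(0, max(1, span - alen)))
        anti_rows.append(
            {
                "chrom": g.chrom,
                "start": a_start,
                "end": min(a_start + alen - 1, g.end),
                "strand": "-" if g.strand == "+" else "+",
            }
        )
        truth_loci[gid]["is_cis_nat"] = True
    # decoys: antisense over a couple of non-expressed genes (must not call)
    non_expr = [g.gene_id for g in genes if not truth_loci[g.gene_id]["expressed"]]
    for gid in non_expr[:2]:
        g = by_id[gid]
        anti_rows.append(
            {
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": "-" if g.strand == "+" else "+",
            }
        )
    antisense = pd.DataFrame(anti_rows, columns=["chrom", "start", "end", "strand"])
    antisense = antisense.sort_values(["start", "end"]).reset_index(drop=True)

    locus_ids = [g.gene_id for g in genes] + ntr_ids
    mat = pd.DataFrame(
        np.vstack([gene_rows[i] for i in locus_ids]),
        index=locus_ids,
        columns=[c.cond_id for c in conditions],
    )
    matrix = ExpressionMatrix(mat, conditions)
    matrix.validate()
    tx_ids = sorted(tx_rows)
    tx_matrix = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([tx_rows[t] for t in tx_ids]) if tx_ids else np.zeros((0, n_cond)),
            index=tx_ids,
            columns=[c.cond_id for c in conditions],
        ),
        conditions,
    )

    truth = {
        "loci": truth_loci,
        "as_events": as_truth,
        "changepoints_bp": [e for _, _, e in regions.regions[:-1]],
        "regions": [list(r) for r in regions.regions],
    }

    return SyntheticDataset(
        config=cfg,
        genes=genes,
        matrix=matrix,
        tx_matrix=tx_matrix,
        ntr_intervals=ntr_intervals,
        sequences=sequences,
        antisense=antisense,
        similarity_flags=similarity_flags,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the generated bundle in the formats io_formats reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "annotation.gff3",
        "matrix": outdir / "fpkm.tsv",
        "tx_matrix": outdir / "fpkm_transcripts.tsv",
        "fasta": outdir / "ntr_sequences.fasta",
        "antisense": outdir / "antisense.tsv",
        "ntr_bed": outdir / "ntr_intervals.bed",
        "similarity": outdir / "ntr_similarity.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    io_formats.write_gff3(ds.genes, paths["gff3"])
    io_formats.write_expression_matrix(ds.matrix, paths["matrix"])
    io_formats.write_expression_matrix(ds.tx_matrix, paths["tx_matrix"])
    io_formats.write_fasta(ds.sequences, paths["fasta"])
    io_formats.write_antisense_table(ds.antisense, paths["antisense"])
    io_formats.write_bed(
        [
            (ds.config.chrom, s, e, nid)
            for nid, (s, e) in sorted(ds.ntr_intervals.items())
        ],
        paths["ntr_bed"],
    )
    with open(paths["similarity"], "w") as fh:
        fh.write("tar_id\thas_protein_similarity\n")
        for nid in sorted(ds.similarity_flags):
            fh.write(f"{nid}\t{int(ds.similarity_flags[nid])}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=0, sort_keys=True)
    ds.config.to_yaml(paths["config"])
    return paths
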
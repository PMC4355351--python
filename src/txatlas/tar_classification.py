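"""Transcriptionally active region (TAR) calling and classification.

A TAR is any locus with FPKM above the floor (default 0, i.e. strictly
positive) in at least one condition. TARs over annotated genes inherit the
gene's category (full vs pseudogene/fragment); expressed loci with no
annotation overlap are novel transcribed regions (NTRs). NTRs are further
screened for putative lincRNAs (length > 200 nt, longest ORF <= 300 AA, no
protein similarity), and expressed genes with opposite-strand transcription
are flagged as cis-NAT producers.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    CATEGORY_PSEUDO,
    CisNatCall,
    ExpressionMatrix,
    GeneModel,
    LincRNACall,
    TAR,
)

log = logging.getLogger(__name__)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def call_tars(
    genes: Sequence[GeneModel],
    matrix: ExpressionMatrix,
    ntr_intervals: Mapping[str, tuple[int, int]],
    fpkm_floor: float = 0.0,
) -> list[TAR]:
    """One TAR per locus expressed (FPKM > floor) in >= 1 condition.

    Every matrix row must be either an annotated gene or a known NTR
    interval; orphan rows are a hard error.
    """
    by_gene = {g.gene_id: g for g in genes}
    # NTR intervals must not overlap annotated gene spans (definition)
    spans = sorted((g.start, g.end) for g in genes)
    starts = np.array([s for s, _ in spans]) if spans else np.array([])
    for nid, (s, e) in ntr_intervals.items():
        idx = int(np.searchsorted(starts, e, side="right")) if len(starts) else 0
        for gs, ge in spans[max(0, idx - 8) : idx + 1]:
            if gs <= e and s <= ge:
                raise ValueError(
                    f"NTR {nid} overlaps an annotated gene span ({gs},{ge})"
                )

    orphans = [
        lid
        for lid in matrix.loci
        if lid not in by_gene and lid not in ntr_intervals
    ]
    if orphans:
        raise ValueError(f"matrix rows without annotation or NTR interval: {orphans[:10]}")

    tars: list[TAR] = []
    expressed_mask = matrix.values > fpkm_floor
    for lid in matrix.loci:
        conds = list(matrix.values.columns[expressed_mask.loc[lid]])
        if not conds:
            continue
        if lid in by_gene:
            g = by_gene[lid]
            tars.append(
                TAR(
                    tar_id=lid,
                    chrom=g.chrom,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    tar_class="gene_pseudo" if g.category == CATEGORY_PSEUDO else "gene_full",
                    gene_id=lid,
                    expressed_conditions=conds,
                )
            )
        else:
            s, e = ntr_intervals[lid]
            tars.append(
                TAR(
                    tar_id=lid,
                    chrom=genes[0].chrom if genes else ".",
                    start=s,
                    end=e,
                    strand=".",
                    tar_class="NTR",
                    gene_id=None,
                    expressed_conditions=conds,
                )
            )
    return tars


def find_longest_orf(sequence: str) -> int:
    """Longest ATG-initiated ORF over all six frames, in amino acids.

    The ORF runs from ATG to the first in-frame stop; its length excludes
    the stop codon (so ``ATGAAATAG`` has length 2). Returns 0 when no
    complete ORF exists.
    """
    if not sequence:
        log.warning("find_longest_orf: empty sequence")
        return 0
    seq = sequence.upper()
    best = 0
    for strand_seq in (seq, seq.translate(_COMPLEMENT)[::-1]):
        for frame in range(3):
            start: Optional[int] = None
            for i in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOP_CODONS:
                    best = max(best, (i - start) // 3)
                    start = None
    return best


def classify_lincRNAs(
    ntr_tars: Sequence[TAR],
    sequences: Mapping[str, str],
    similarity_flags: Mapping[str, bool],
    min_length_nt: int = 200,
    max_orf_aa: int = 300,
) -> list[LincRNACall]:
    """Apply the three lincRNA filters conjunctively to NTR TARs.

    A putative lincRNA is longer than ``min_length_nt`` (strict), carries no
    ORF longer than ``max_orf_aa`` (an ORF of exactly the bound passes), and
    has no protein similarity. TARs without a sequence are marked uncallable.
    """
    calls = []
    for tar in ntr_tars:
        similar = bool(similarity_flags.get(tar.tar_id, False))
        seq = sequences.get(tar.tar_id)
        if seq is None:
            log.warning("lincRNA call: no sequence for %s; marked uncallable", tar.tar_id)
            calls.append(
                LincRNACall(tar.tar_id, None, None, similar, False, uncallable=True)
            )
            continue
        length = len(seq)
        orf = find_longest_orf(seq)
        is_linc = (length > min_length_nt) and (orf <= max_orf_aa) and not similar
        calls.append(LincRNACall(tar.tar_id, length, orf, similar, is_linc))
    return calls


def detect_cis_nats(
    genes: Sequence[GeneModel],
    antisense_table: pd.DataFrame,
    expressed_ids: set[str],
    min_overlap_bp: int = 1,
) -> list[CisNatCall]:
    """Flag expressed genes overlapped by opposite-strand transcription.

    ``antisense_table`` holds stranded intervals (chrom, start, end, strand).
    A gene is a cis-NAT producer iff it is expressed and the total
    opposite-strand overlap reaches ``min_overlap_bp``.
    """
    chroms = {g.chrom for g in genes}
    unknown = set(antisense_table["chrom"]) - chroms
    if unknown:
        raise ValueError(f"antisense intervals on unknown chromosome(s): {sorted(unknown)}")

    calls = []
    for g in genes:
        anti = antisense_table[
            (antisense_table["chrom"] == g.chrom)
            & (antisense_table["strand"] != g.strand)
        ]
        ov_start = np.maximum(anti["start"].to_numpy(), g.start)
        ov_end = np.minimum(anti["end"].to_numpy(), g.end)
        overlap = int(np.clip(ov_end - ov_start + 1, 0, None).sum())
        is_nat = (g.gene_id in expressed_ids) and overlap >= min_overlap_bp
        calls.append(CisNatCall(g.gene_id, overlap, is_nat))
    return calls


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


def summary_from_counts(
    predicted_full: int,
    predicted_pseudo: int,
    expressed_full: int,
    expressed_pseudo: int,
    n_ntr: int,
    chrom_length_bp: Optional[int] = None,
    n_lincRNA: Optional[int] = None,
    n_protein_similar_ntr: Optional[int] = None,
    n_cis_nat: Optional[int] = None,
    n_multicopy_pseudo: Optional[int] = None,
) -> dict:
    """Headline TAR summary computed from class counts.

    All percentages are reported to one decimal; the mean TAR spacing (kb)
    is chromosome length divided by the TAR count.
    """
    predicted = predicted_full + predicted_pseudo
    expressed = expressed_full + expressed_pseudo
    n_tars = expressed + n_ntr
    out = {
        "predicted_genes": predicted,
        "expressed_genes": expressed,
        "n_tars": n_tars,
        "pct_gene_models_expressed": _pct(expressed, predicted),
        "pct_full_expressed": _pct(expressed_full, predicted_full),
        "pct_pseudo_expressed": _pct(expressed_pseudo, predicted_pseudo),
        "n_ntr": n_ntr,
        "pct_ntr_of_tars": _pct(n_ntr, n_tars),
    }
    if chrom_length_bp is not None and n_tars:
        out["mean_tar_spacing_kb"] = round(chrom_length_bp / 1000.0 / n_tars, 1)
    if n_lincRNA is not None:
        out["n_lincRNA"] = n_lincRNA
    if n_protein_similar_ntr is not None:
        out["n_protein_similar_ntr"] = n_protein_similar_ntr
    if n_cis_nat is not None:
        out["n_cis_nat"] = n_cis_nat
        out["pct_cis_nat_of_expressed"] = _pct(n_cis_nat, expressed)
    if n_multicopy_pseudo is not None:
        out["n_multicopy_pseudo"] = n_multicopy_pseudo
        out["pct_multicopy_pseudo"] = _pct(n_multicopy_pseudo, expressed_pseudo)
    return out


def summarize_tars(
    tars: Sequence[TAR],
    genes: Sequence[GeneModel],
    chrom_length_bp: Optional[int] = None,
    lincrna_calls: Optional[Sequence[LincRNACall]] = None,
    similarity_flags: Optional[Mapping[str, bool]] = None,
    cis_nat_calls: Optional[Sequence[CisNatCall]] = None,
) -> dict:
    """Table-style summary (counts + percentages per class) from TAR calls."""
    predicted_full = sum(1 for g in genes if g.category != CATEGORY_PSEUDO)
    predicted_pseudo = sum(1 for g in genes if g.category == CATEGORY_PSEUDO)
    expressed_full = sum(1 for t in tars if t.tar_class == "gene_full")
    expressed_pseudo = sum(1 for t in tars if t.tar_class == "gene_pseudo")
    ntr_ids = {t.tar_id for t in tars if t.tar_class == "NTR"}
    n_linc = (
        sum(1 for c in lincrna_calls if c.is_lincRNA) if lincrna_calls is not None else None
    )
    n_sim = (
        sum(1 for nid in ntr_ids if similarity_flags.get(nid, False))
        if similarity_flags is not None
        else None
    )
    n_nat = (
        sum(1 for c in cis_nat_calls if c.is_cis_nat) if cis_nat_calls is not None else None
    )
    return summary_from_counts(
        predicted_full,
        predicted_pseudo,
        expressed_full,
        expressed_pseudo,
        len(ntr_ids),
        chrom_length_bp=chrom_length_bp,
        n_lincRNA=n_linc,
        n_protein_similar_ntr=n_sim,
        n_cis_nat=n_nat,
    )


def tars_to_table(tars: Sequence[TAR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tar_id": [t.tar_id for t in tars],
            "chrom": [t.chrom for t in tars],
            "start": [t.start for t in tars],
            "end": [t.end for t in tars],
            "strand": [t.strand for t in tars],
            "class": [t.tar_class for t in tars],
            "n_expressed_conditions": [len(t.expressed_conditions) for t in tars],
        }
    )
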
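"""Alternative-splicing event classification among a gene's isoforms.

Events are called from pairwise comparison of exon chains using the five
canonical structural definitions, strand-aware for the splice-site types:

IR    an intron of one isoform lies fully inside a single exon of the other.
ES    an exon of one isoform lies fully inside a single intron of the other
      and the flanking exons' inner boundaries are shared.
A5SS  two overlapping exons share their acceptor-side boundary and differ at
      the donor side (donor = exon end on '+', exon start on '-'); the exon
      across the differing-side intron must share its inner boundary in both
      isoforms, so that an intron-retention pair is not also called A5SS.
A3SS  the mirror case.
MXE   exons x (only in isoform A) and y (only in B), non-overlapping, both
      single exons between the same shared flanking exon pair.

Terminal-exon differences (alternative first/last exons) are not events.
Pairwise calls are deduplicated by (type, coordinates) across all isoform
pairs; a pair whose internal structure differs without matching any canonical
pattern yields a single event of type ``complex``, which is excluded from the
five-type proportion denominator.
"""
from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

from .models import ASEvent, ExpressionMatrix, GeneModel, Interval, TranscriptModel

AS_TYPES = ("IR", "ES", "A3SS", "A5SS", "MXE")


def _contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _ir_events(x: TranscriptModel, y: TranscriptModel) -> list[tuple[str, tuple]]:
    """Introns of x retained inside a single exon of y."""
    out = []
    for intron in x.introns:
        if any(_contains(exon, intron) for exon in y.exons):
            out.append(("IR", intron))
    return out


def _es_events(x: TranscriptModel, y: TranscriptModel) -> list[tuple[str, tuple]]:
    """Internal exons of x skipped in y (exon inside a single intron of y,
    flanking inner boundaries shared)."""
    out = []
    for j in range(1, x.n_exons - 1):
        exon = x.exons[j]
        prev_end = x.exons[j - 1][1]
        next_start = x.exons[j + 1][0]
        for k, intron in enumerate(y.introns):
            if _contains(intron, exon):
                if y.exons[k][1] == prev_end and y.exons[k + 1][0] == next_start:
                    out.append(("ES", exon))
                break
    return out


def _altss_events(
    a: TranscriptModel, b: TranscriptModel, strand: str
) -> list[tuple[str, tuple]]:
    out = []
    for i, ea in enumerate(a.exons):
        for j, eb in enumerate(b.exons):
            if ea == eb or not _overlap(ea, eb):
                continue
            if ea[0] == eb[0] and ea[1] != eb[1]:
                # variation on the right-hand side; internal boundaries only,
                # and the exon across the right intron must share its start
                if i + 1 < a.n_exons and j + 1 < b.n_exons:
                    if a.exons[i + 1][0] == b.exons[j + 1][0]:
                        etype = "A5SS" if strand == "+" else "A3SS"
                        coords = (min(ea[1], eb[1]) + 1, max(ea[1], eb[1]))
                        out.append((etype, coords))
            elif ea[1] == eb[1] and ea[0] != eb[0]:
                # variation on the left-hand side
                if i > 0 and j > 0:
                    if a.exons[i - 1][1] == b.exons[j - 1][1]:
                        etype = "A3SS" if strand == "+" else "A5SS"
                        coords = (min(ea[0], eb[0]), max(ea[0], eb[0]) - 1)
                        out.append((etype, coords))
    return out


def _mxe_events(a: TranscriptModel, b: TranscriptModel) -> list[tuple[str, tuple]]:
    shared = set(a.exons) & set(b.exons)
    out = []
    for i in range(a.n_exons - 2):
        f1, x, f2 = a.exons[i], a.exons[i + 1], a.exons[i + 2]
        if f1 not in shared or f2 not in shared:
            continue
        if any(_overlap(x, eb) for eb in b.exons):
            continue  # x must be absent from b
        j1 = b.exons.index(f1)
        if j1 + 2 >= b.n_exons or b.exons[j1 + 2] != f2:
            continue
        y = b.exons[j1 + 1]
        if _overlap(x, y) or any(_overlap(y, ea) for ea in a.exons):
            continue
        pair = tuple(sorted((x, y)))
        out.append(("MXE", pair))
    return out


def _internal_signature(tx: TranscriptModel) -> tuple:
    """Exon chain with the outermost (TSS/TES) endpoints masked."""
    ex = list(tx.exons)
    if len(ex) == 1:
        return ("single",)
    first = (None, ex[0][1])
    last = (ex[-1][0], None)
    return tuple([first] + ex[1:-1] + [last])


def classify_pair(
    a: TranscriptModel, b: TranscriptModel, strand: str
) -> list[tuple[str, tuple]]:
    """All canonical events distinguishing one isoform pair (symmetric)."""
    events: list[tuple[str, tuple]] = []
    events += _ir_events(a, b) + _ir_events(b, a)
    events += _es_events(a, b) + _es_events(b, a)
    events += _altss_events(a, b, strand)
    events += _mxe_events(a, b) + _mxe_events(b, a)
    events = sorted(set(events))
    if not events and _internal_signature(a) != _internal_signature(b):
        lo = min(a.span[0], b.span[0])
        hi = max(a.span[1], b.span[1])
        events = [("complex", (lo, hi))]
    return events


def classify_as_events(gene: GeneModel) -> list[ASEvent]:
    """Classify AS events among all isoform pairs of a gene, deduplicated.

    Single-isoform genes return an empty list.
    """
    seen: dict[tuple, ASEvent] = {}
    for a, b in combinations(sorted(gene.transcripts, key=lambda t: t.tx_id), 2):
        for etype, coords in classify_pair(a, b, gene.strand):
            key = (etype, coords)
            if key not in seen:
                seen[key] = ASEvent(
                    gene_id=gene.gene_id,
                    event_type=etype,
                    coords=coords,
                    witnesses=(a.tx_id, b.tx_id),
                )
    return sorted(seen.values(), key=lambda e: (str(e.coords), e.event_type))


def as_summary(
    genes: Sequence[GeneModel],
    events: Sequence[ASEvent],
    tx_matrix: Optional[ExpressionMatrix] = None,
) -> dict:
    """Summarize AS rates and event-type proportions.

    ``genes`` should be the expressed genes under study. When a
    transcript-level FPKM matrix is supplied, the percentage of transcripts
    present (FPKM > 0) in all conditions is reported as well.
    """
    n_genes = len(genes)
    n_multi_iso = sum(1 for g in genes if len(g.transcripts) >= 2)
    multiexonic = [g for g in genes if g.primary_transcript.n_exons >= 2]
    n_multiexonic_as = sum(1 for g in multiexonic if len(g.transcripts) >= 2)
    n_tx = sum(len(g.transcripts) for g in genes)

    type_counts = Counter(e.event_type for e in events if e.event_type in AS_TYPES)
    n_canonical = sum(type_counts.values())
    proportions = {
        t: (type_counts[t] / n_canonical if n_canonical else 0.0) for t in AS_TYPES
    }

    pct_tx_all_conditions = None
    if tx_matrix is not None:
        tx_ids = {tx.tx_id for g in genes for tx in g.transcripts}
        sub = tx_matrix.values.loc[tx_matrix.values.index.isin(tx_ids)]
        if len(sub):
            pct_tx_all_conditions = round(
                100.0 * ((sub > 0).all(axis=1)).mean(), 1
            )

    return {
        "n_genes": n_genes,
        "n_transcripts": n_tx,
        "mean_isoforms_per_gene": round(n_tx / n_genes, 1) if n_genes else 0.0,
        "pct_genes_alternatively_spliced": round(100.0 * n_multi_iso / n_genes, 1)
        if n_genes
        else 0.0,
        "pct_multiexonic_genes_as": round(
            100.0 * n_multiexonic_as / len(multiexonic), 1
        )
        if multiexonic
        else 0.0,
        "n_events": n_canonical,
        "n_complex_events": sum(1 for e in events if e.event_type == "complex"),
        "event_type_counts": dict(type_counts),
        "event_type_proportions": proportions,
        "pct_transcripts_in_all_conditions": pct_tx_all_conditions,
    }


def mean_isoforms_from_counts(n_transcripts: int, n_genes: int) -> float:
    """Average transcripts per expressed gene from summary counts."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round(n_transcripts / n_genes, 1)


def events_to_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "type": [e.event_type for e in events],
            "coords": [str(e.coords) for e in events],
            "witness_a": [e.witnesses[0] for e in events],
            "witness_b": [e.witnesses[1] for e in events],
        }
    )
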
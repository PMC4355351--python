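"""Core data model for a chromosome-scale transcriptome map.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout
the package; conversion to 0-based half-open happens only when writing BED.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """One isoform: an ordered chain of genomic exons.

    Exons are (start, end) pairs, 1-based inclusive, sorted ascending and
    non-overlapping. Introns are the gaps between consecutive exons.
    """

    tx_id: str
    gene_id: str
    exons: list[Interval]
    sequence: Optional[str] = None

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.tx_id}: needs at least one exon")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"transcript {self.tx_id}: exon end < start ({s},{e})")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.tx_id}: exons not sorted")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.tx_id}: overlapping exons ({s1},{e1}) ({s2},{e2})"
                )

    @property
    def introns(self) -> list[Interval]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced transcript length = sum of exon lengths."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cumulative_intron_length(self) -> int:
        return sum(e - s + 1 for s, e in self.introns)


CATEGORY_FULL = "full"
CATEGORY_PSEUDO = "pseudogene_fragment"


@dataclass
class GeneModel:
    """A located, stranded gene with category flags and child transcripts."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str = CATEGORY_FULL
    syntenic: bool = False
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def validate(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.category not in (CATEGORY_FULL, CATEGORY_PSEUDO):
            raise ValueError(f"gene {self.gene_id}: unknown category {self.category!r}")
        for tx in self.transcripts:
            tx.validate()
            s, e = tx.span
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {tx.tx_id} outside gene span"
                )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def primary_transcript(self) -> TranscriptModel:
        """Longest isoform; ties broken by transcript id."""
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        return max(self.transcripts, key=lambda t: (t.length, t.tx_id))


@dataclass(frozen=True)
class Condition:
    """One experimental condition, e.g. an organ at a developmental stage."""

    cond_id: str
    organ: str
    stage: str

    @classmethod
    def parse(cls, cond_id: str) -> "Condition":
        if ":" in cond_id:
            organ, stage = cond_id.split(":", 1)
        else:
            organ, stage = cond_id, ""
        return cls(cond_id, organ, stage)


@dataclass
class ExpressionMatrix:
    """Loci x conditions FPKM table with condition metadata.

    ``values`` is a DataFrame indexed by locus id; columns are condition ids.
    """

    values: pd.DataFrame
    conditions: list[Condition]

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated locus ids: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values are not allowed")
        if list(self.values.columns) != [c.cond_id for c in self.conditions]:
            raise ValueError("condition metadata does not match matrix columns")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        m = cls(df, [Condition.parse(c) for c in df.columns])
        m.validate()
        return m


@dataclass
class TAR:
    """A transcriptionally active region (FPKM > floor in >= 1 condition)."""

    tar_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '.' when unknown (unstranded NTRs)
    tar_class: str  # gene_full | gene_pseudo | NTR
    gene_id: Optional[str]
    expressed_conditions: list[str]


@dataclass
class LincRNACall:
    tar_id: str
    length_nt: Optional[int]
    longest_orf_aa: Optional[int]
    has_protein_similarity: bool
    is_lincRNA: bool
    uncallable: bool = False


@dataclass
class CisNatCall:
    gene_id: str
    antisense_overlap_bp: int
    is_cis_nat: bool


@dataclass
class ExpressionProfile:
    locus_id: str
    breadth: int
    mean_expr: float  # mean FPKM over conditions where expressed; 0 if none
    expressed: bool
    level_class: Optional[str]  # low | medium | high; None when not expressed
    organ_specific: Optional[str]  # organ label iff all expression in one organ


@dataclass
class ASEvent:
    gene_id: str
    event_type: str  # IR | ES | A3SS | A5SS | MXE | complex
    coords: tuple  # (start, end) or ((s1,e1),(s2,e2)) for MXE
    witnesses: tuple[str, str]

    def key(self) -> tuple:
        return (self.event_type, self.coords)


@dataclass
class WindowTrack:
    chrom: str
    window: int
    step: int
    starts: np.ndarray  # window start positions, bp (0-based starts of windows)
    values: np.ndarray
    zscores: Optional[np.ndarray] = None

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass
class SegmentationResult:
    changepoints: list[int]  # indices: last index of each left segment
    changepoint_bp: list[int]
    segment_means: list[float]
    penalty: float
    method: str = "binseg-bic-mean"


@dataclass
class RegionTable:
    """Named, ordered, non-overlapping regions tiling [0, L] (bp)."""

    regions: list[tuple[str, int, int]]

    def validate(self) -> None:
        prev_end = None
        for name, s, e in self.regions:
            if e <= s:
                raise ValueError(f"region {name}: end <= start")
            if prev_end is not None and s != prev_end:
                raise ValueError(f"region {name}: regions must tile without gaps")
            prev_end = e

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.regions]

    @property
    def length(self) -> int:
        return self.regions[-1][2]


@dataclass
class Insula:
    members: list[str]  # gene ids in genomic order
    start: int
    end: int
    internal_gaps: list[int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class NeighborPair:
    gene_a: str
    gene_b: str
    same_cluster: bool
    orientation: str  # divergent | convergent | tandem
    intergenic_bp: int
    duplicated_pair: bool = False


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]  # locus id -> cluster id (0 = constant-profile bin)
    cut_similarity: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))
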
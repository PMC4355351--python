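"""Readers and writers for the plain-text formats the pipeline touches.

GFF3 (gene/mRNA/exon), FASTA, BED6 output, and tab-separated matrices and
tables. Internal coordinates are 1-based inclusive everywhere; BED files are
converted to 0-based half-open at the write boundary only.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CATEGORY_FULL,
    CATEGORY_PSEUDO,
    Condition,
    ExpressionMatrix,
    GeneModel,
    TranscriptModel,
)

log = logging.getLogger(__name__)

_KNOWN_FEATURES = {"gene", "mRNA", "exon"}


def _parse_attrs(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(
    path: str | Path,
    category_key: str = "category",
    syntenic_key: str = "syntenic",
) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/exon features into GeneModels.

    Unknown feature types are ignored with a logged warning. Category and
    synteny flags are read from configurable attribute keys and default to
    ``full`` / ``False`` when absent.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    tx_parent: dict[str, str] = {}
    warned_types: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start ({start} > {end})")
            attrs = _parse_attrs(attrs_s)

            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID attribute")
                category = attrs.get(category_key, CATEGORY_FULL)
                if category not in (CATEGORY_FULL, CATEGORY_PSEUDO):
                    raise ValueError(f"{path}:{lineno}: unknown category {category!r}")
                syntenic = attrs.get(syntenic_key, "false").lower() in ("true", "1", "yes")
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=chrom, start=start, end=end, strand=strand,
                    category=category, syntenic=syntenic, transcripts=[],
                )
            elif ftype == "mRNA":
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"{path}:{lineno}: mRNA needs ID and Parent")
                transcripts[tid] = TranscriptModel(tx_id=tid, gene_id=parent, exons=[])
                tx_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    raise ValueError(
                        f"{path}:{lineno}: exon without known mRNA parent"
                    )
                transcripts[parent].exons.append((start, end))
            else:
                if ftype not in warned_types:
                    warned_types.add(ftype)
                    log.warning("%s: ignoring unknown feature type %r", path, ftype)

    for tid, tx in transcripts.items():
        tx.exons.sort()
        parent = tx_parent[tid]
        if parent not in genes:
            raise ValueError(f"mRNA {tid}: parent gene {parent} not found")
        genes[parent].transcripts.append(tx)

    out = list(genes.values())
    for g in out:
        g.transcripts.sort(key=lambda t: t.tx_id)
        g.validate()
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels back out; round-trips bit-exact with read_gff3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};category={g.category};syntenic={'true' if g.syntenic else 'false'}"
            fh.write(
                f"{g.chrom}\ttxatlas\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx in g.transcripts:
                fh.write(
                    f"{g.chrom}\ttxatlas\tmRNA\t{tx.span[0]}\t{tx.span[1]}\t.\t{g.strand}\t.\t"
                    f"ID={tx.tx_id};Parent={g.gene_id}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{g.chrom}\ttxatlas\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tx.tx_id}\n"
                    )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a locus x condition FPKM table (TSV, first column = locus id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated locus ids {dups}")
    num = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            num[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric FPKM at row {bad!r}, column {col!r}"
            ) from None
    if (num.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    m = ExpressionMatrix(num.astype(float), [Condition.parse(c) for c in df.columns])
    m.validate()
    return m


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="locus", float_format="%.6g")


def write_bed(
    intervals: Iterable[tuple],
    path: str | Path,
    chrom_length: Optional[int] = None,
) -> None:
    """Write 1-based inclusive intervals as BED6 (0-based half-open).

    Each interval is ``(chrom, start, end[, name[, score[, strand]]])``.
    """
    rows = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        name = iv[3] if len(iv) > 3 and iv[3] is not None else "."
        score = iv[4] if len(iv) > 4 and iv[4] is not None else "."
        strand = iv[5] if len(iv) > 5 and iv[5] is not None else "."
        if start < 1 or (chrom_length is not None and end > chrom_length):
            raise ValueError(f"interval ({chrom},{start},{end}) outside chromosome bounds")
        rows.append(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n")
    with open(path, "w") as fh:
        fh.write("# BED6: chrom, 0-based start, end, name, score, strand\n")
        fh.writelines(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_antisense_table(path: str | Path) -> pd.DataFrame:
    """Stranded antisense transcription intervals: chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_antisense_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Gene -> set of terms, from a two-column TSV (gene_id, term)."""
    df = pd.read_csv(path, sep="\t", names=["gene_id", "term"], header=None, dtype=str)
    out: dict[str, set[str]] = {}
    for gid, term in zip(df["gene_id"], df["term"]):
        out.setdefault(gid, set()).add(term)
    return out
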
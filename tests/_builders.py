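"""Small builders for hand-made genes and matrices used across tests."""
from __future__ import annotations

import numpy as np
import pandas as pd

from txatlas.models import ExpressionMatrix, GeneModel, TranscriptModel

CONDITIONS = [f"{o}:{s}" for o in ("leaf", "shoot", "root", "spike", "grain")
              for s in ("1", "2", "3")]


def make_tx(exons, tx_id="T1", gene_id="G1"):
    tx = TranscriptModel(tx_id=tx_id, gene_id=gene_id, exons=list(exons))
    tx.validate()
    return tx


def make_gene(transcripts, gene_id="G1", chrom="chr1", strand="+",
              category="full", start=None, end=None):
    start = start if start is not None else min(t.span[0] for t in transcripts)
    end = end if end is not None else max(t.span[1] for t in transcripts)
    g = GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end,
                  strand=strand, category=category,
                  transcripts=list(transcripts))
    g.validate()
    return g


def make_matrix(rows: dict[str, list[float]], columns=None) -> ExpressionMatrix:
    cols = columns or CONDITIONS[: len(next(iter(rows.values())))]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(float)
    return ExpressionMatrix.from_dataframe(df)


def random_primary(rng: np.random.Generator, gene_id: str, start: int,
                   n_exons: int) -> TranscriptModel:
    """A primary transcript with roomy introns (every AS type feasible)."""
    exons = []
    pos = start
    for i in range(n_exons):
        exon_len = int(rng.integers(80, 300))
        exons.append((pos, pos + exon_len - 1))
        pos = exons[-1][1] + 1 + int(rng.integers(150, 500))
    return make_tx(exons, tx_id=f"{gene_id}.1", gene_id=gene_id)
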
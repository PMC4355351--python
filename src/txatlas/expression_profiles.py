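"""Expression breadth, level classes, and the expression-vs-structure binning.

Breadth is the number of conditions with FPKM > 0; the mean expression level
averages FPKM over the conditions where the locus is expressed only. Level
classes follow the semi-quantitative FPKM scale: low < 5, medium in [5, 200),
high >= 200. Expressed loci are ranked by mean expression and split into
equal-size bins (30 by default) to expose the non-monotonic (bell-shaped)
relationship between expression level and gene structure.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, ExpressionProfile, GeneModel

log = logging.getLogger(__name__)

LEVEL_LOW_CUT = 5.0
LEVEL_HIGH_CUT = 200.0

STRUCTURE_FEATURES = (
    "transcript_length",
    "n_exons",
    "cumulative_intron_length",
    "mean_exon_length",
    "mean_intron_length",
    "n_isoforms",
)


def level_class(mean_expr: float) -> str:
    if mean_expr < LEVEL_LOW_CUT:
        return "low"
    if mean_expr < LEVEL_HIGH_CUT:
        return "medium"
    return "high"


def profile_expression(matrix: ExpressionMatrix) -> list[ExpressionProfile]:
    """Per-locus breadth, mean expression over expressed conditions, level
    class, and organ-specificity (all expressed conditions in one organ)."""
    organ_by_cond = {c.cond_id: c.organ for c in matrix.conditions}
    profiles = []
    vals = matrix.values
    for lid in vals.index:
        row = vals.loc[lid]
        pos = row[row > 0]
        breadth = int(len(pos))
        if breadth == 0:
            profiles.append(ExpressionProfile(lid, 0, 0.0, False, None, None))
            continue
        mean_expr = float(pos.mean())
        organs = {organ_by_cond[c] for c in pos.index}
        organ = organs.pop() if len(organs) == 1 else None
        profiles.append(
            ExpressionProfile(lid, breadth, mean_expr, True, level_class(mean_expr), organ)
        )
    return profiles


def breadth_distribution(
    profiles: Sequence[ExpressionProfile],
    categories: Mapping[str, set[str]],
    max_breadth: Optional[int] = None,
) -> pd.DataFrame:
    """Per-category percentage of expressed loci at each breadth 1..n.

    ``categories`` maps category name -> set of locus ids. Percentages sum
    to 100 within each category; empty categories are omitted with a warning.
    """
    expressed = [p for p in profiles if p.expressed]
    if max_breadth is None:
        max_breadth = max((p.breadth for p in expressed), default=1)
    rows = {}
    for name, ids in categories.items():
        members = [p for p in expressed if p.locus_id in ids]
        if not members:
            log.warning("breadth_distribution: empty category %r omitted", name)
            continue
        counts = np.zeros(max_breadth)
        for p in members:
            counts[p.breadth - 1] += 1
        rows[name] = 100.0 * counts / counts.sum()
    return pd.DataFrame(rows, index=pd.RangeIndex(1, max_breadth + 1, name="breadth"))


def gene_structure_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Structural features per gene, computed on the primary (longest)
    transcript: spliced length, exon count, cumulative/mean intron length,
    mean exon length, isoform count."""
    rows = []
    for g in genes:
        tx = g.primary_transcript
        n_introns = tx.n_exons - 1
        rows.append(
            {
                "locus_id": g.gene_id,
                "transcript_length": tx.length,
                "n_exons": tx.n_exons,
                "cumulative_intron_length": tx.cumulative_intron_length,
                "mean_exon_length": tx.length / tx.n_exons,
                "mean_intron_length": (
                    tx.cumulative_intron_length / n_introns if n_introns else 0.0
                ),
                "n_isoforms": len(g.transcripts),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def bin_by_expression(
    profiles: Sequence[ExpressionProfile],
    structures: pd.DataFrame,
    n_bins: int = 30,
) -> pd.DataFrame:
    """Rank expressed loci by mean expression and split into ``n_bins``
    contiguous equal-size bins (sizes differ by at most one; ties broken by
    locus id). Returns a tidy frame: bin, feature, mean, sd, n, plus the
    per-bin mean expression for reference.
    """
    expressed = [p for p in profiles if p.expressed and p.locus_id in structures.index]
    if len(expressed) < n_bins:
        raise ValueError(f"{len(expressed)} expressed loci < {n_bins} bins")
    order = sorted(expressed, key=lambda p: (p.mean_expr, p.locus_id))
    ids = [p.locus_id for p in order]
    breadth = {p.locus_id: p.breadth for p in order}
    mean_expr = {p.locus_id: p.mean_expr for p in order}
    chunks = np.array_split(np.arange(len(ids)), n_bins)

    features = [c for c in STRUCTURE_FEATURES if c in structures.columns]
    rows = []
    for b, idx in enumerate(chunks, start=1):
        members = [ids[i] for i in idx]
        sub = structures.loc[members]
        for feat in features:
            v = sub[feat].to_numpy(dtype=float)
            rows.append(
                {"bin": b, "feature": feat, "mean": v.mean(), "sd": v.std(ddof=0),
                 "n": len(members)}
            )
        bvals = np.array([breadth[m] for m in members], dtype=float)
        rows.append(
            {"bin": b, "feature": "breadth", "mean": bvals.mean(),
             "sd": bvals.std(ddof=0), "n": len(members)}
        )
        evals = np.array([mean_expr[m] for m in members])
        rows.append(
            {"bin": b, "feature": "mean_expr", "mean": evals.mean(),
             "sd": evals.std(ddof=0), "n": len(members)}
        )
    return pd.DataFrame(rows)


def detect_inflexion(bins: pd.DataFrame, feature: str) -> tuple[int, bool]:
    """Bin index (1-based) of the maximum of a 3-bin moving average of the
    per-bin means, plus a ``monotone`` flag set when the maximum sits on the
    boundary (no interior peak)."""
    sub = bins[bins["feature"] == feature].sort_values("bin")
    if len(sub) < 5:
        raise ValueError("need at least 5 bins")
    means = sub["mean"].to_numpy(dtype=float)
    padded = np.concatenate([[means[0]], means, [means[-1]]])
    smooth = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    idx = int(np.argmax(smooth))
    monotone = idx in (0, len(means) - 1)
    return idx + 1, monotone


def outlier_statistic(values: Sequence[float]) -> dict:
    """Interquartile outlier screen on positive values.

    Reports linear-interpolation (type-7) quartiles, the spread statistic
    (Q3 - Q1) * 3 / Q3, and the indices flagged by the conventional fence
    rule value > Q3 + 3 * (Q3 - Q1). Both are returned; the fence drives any
    exclusion.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    if q3 == 0:
        log.warning("outlier_statistic: Q3 = 0, statistic undefined")
        stat = float("nan")
    else:
        stat = (q3 - q1) * 3.0 / q3
    fence = q3 + 3.0 * (q3 - q1)
    flagged = [int(i) for i in np.nonzero(v > fence)[0]]
    return {"q1": float(q1), "q3": float(q3), "statistic": float(stat),
            "fence": float(fence), "outlier_indices": flagged}
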
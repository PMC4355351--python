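"""Co-expression clustering, gene islands (insulae), and enrichment tests.

Expression profiles are clustered by complete-linkage agglomeration on the
distance 1 - Pearson correlation, with the dendrogram cut at a similarity
threshold (0.641 by default -- the two-sided critical Pearson correlation at
alpha = 0.01 for 15 paired observations). Insulae are maximal runs of >= 2
neighboring genes whose intergenic distances stay at or below a gap
threshold (30 kb by default); adjacent insula members sharing a cluster
define co-expressed gene pairs, annotated with transcription orientation.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .models import ClusterAssignment, GeneModel, Insula, NeighborPair, RegionTable
from .chromosome_partition import assign_region

log = logging.getLogger(__name__)

DEFAULT_CUT_SIMILARITY = 0.641
DEFAULT_GAP_THRESHOLD = 30_000
CONSTANT_PROFILE_CLUSTER = 0


def critical_pearson(n: int, alpha: float) -> float:
    """Two-sided critical Pearson correlation at significance ``alpha`` for
    ``n`` paired observations: r = t / sqrt(t^2 + n - 2) with t the
    (1 - alpha/2) Student-t quantile at n - 2 degrees of freedom."""
    if n < 4:
        raise ValueError("need n >= 4")
    if alpha >= 1.0:
        return 0.0
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def cluster_profiles(
    profiles: pd.DataFrame,
    cut_similarity: float = DEFAULT_CUT_SIMILARITY,
) -> ClusterAssignment:
    """Complete-linkage clustering of expression profiles.

    ``profiles`` is a loci x conditions frame (expressed loci). Distance is
    1 - Pearson; the tree is cut at distance 1 - cut_similarity. Loci are
    sorted by id first, so the result is deterministic. Constant
    (zero-variance) profiles have undefined correlation; they are placed in
    the reserved cluster 0 and excluded from the linkage.
    """
    profiles = profiles.sort_index()
    assignments: dict[str, int] = {}
    var = profiles.var(axis=1, ddof=0)
    constant = var[var == 0].index
    for lid in constant:
        assignments[lid] = CONSTANT_PROFILE_CLUSTER
    active = profiles.drop(index=constant)
    if len(active) == 0:
        return ClusterAssignment(assignments, cut_similarity)
    if len(active) == 1:
        assignments[active.index[0]] = 1
        return ClusterAssignment(assignments, cut_similarity)

    corr = np.corrcoef(active.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="complete")
    flat = fcluster(tree, t=1.0 - cut_similarity, criterion="distance")

    # relabel clusters 1..k in order of first appearance for determinism
    relabel: dict[int, int] = {}
    for lid, c in zip(active.index, flat):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        assignments[lid] = relabel[c]
    return ClusterAssignment(assignments, cut_similarity)


def detect_insulae(
    genes: Sequence[GeneModel],
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> list[Insula]:
    """Maximal runs of >= 2 consecutive genes with intergenic distance at or
    below the threshold. Overlapping genes count as distance 0 (warned).
    Singletons are not insulae."""
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    insulae: list[Insula] = []
    run: list[GeneModel] = []
    gaps: list[int] = []

    def flush() -> None:
        if len(run) >= 2:
            insulae.append(
                Insula(
                    members=[g.gene_id for g in run],
                    start=run[0].start,
                    end=max(g.end for g in run),
                    internal_gaps=list(gaps),
                )
            )

    for g in ordered:
        if not run:
            run, gaps = [g], []
            continue
        prev = run[-1]
        d = g.start - prev.end - 1
        if d < 0:
            log.warning("overlapping genes %s and %s; distance clamped to 0",
                        prev.gene_id, g.gene_id)
            d = 0
        if d <= gap_threshold:
            run.append(g)
            gaps.append(d)
        else:
            flush()
            run, gaps = [g], []
    flush()
    return insulae


def insulae_summary(insulae: Sequence[Insula], n_genes_total: int) -> dict:
    n_in = sum(i.size for i in insulae)
    return {
        "n_insulae": len(insulae),
        "genes_in_insulae": n_in,
        "pct_genes_in_insulae": round(100.0 * n_in / n_genes_total, 1)
        if n_genes_total
        else 0.0,
        "mean_genes_per_insula": round(n_in / len(insulae), 1) if insulae else 0.0,
    }


def pair_orientation(strand_upstream: str, strand_downstream: str) -> str:
    """Orientation of an adjacent gene pair in genomic order: divergent when
    the 5' ends face each other (upstream on '-', downstream on '+'),
    convergent for '+/-', tandem otherwise."""
    if strand_upstream == "-" and strand_downstream == "+":
        return "divergent"
    if strand_upstream == "+" and strand_downstream == "-":
        return "convergent"
    return "tandem"


def coexpressed_pairs(
    insulae: Sequence[Insula],
    clusters: Mapping[str, int],
    genes: Sequence[GeneModel],
    duplication_flags: Optional[Mapping[frozenset, bool]] = None,
) -> tuple[list[NeighborPair], dict]:
    """Adjacent pairs within insulae, flagged for shared expression cluster.

    ``duplication_flags`` maps frozenset({gene_a, gene_b}) -> bool (input
    paralogy annotation). The summary counts co-expressed pairs, the
    distinct genes they involve (chains make this less than twice the pair
    count), the duplicated fraction, and the mean intergenic distance of
    co-expressed pairs.
    """
    by_id = {g.gene_id: g for g in genes}
    duplication_flags = duplication_flags or {}
    pairs: list[NeighborPair] = []
    for ins in insulae:
        for a, b, gap in zip(ins.members, ins.members[1:], ins.internal_gaps):
            ga, gb = by_id[a], by_id[b]
            same = (
                a in clusters and b in clusters and clusters[a] == clusters[b]
            )
            pairs.append(
                NeighborPair(
                    gene_a=a,
                    gene_b=b,
                    same_cluster=bool(same),
                    orientation=pair_orientation(ga.strand, gb.strand),
                    intergenic_bp=gap,
                    duplicated_pair=bool(duplication_flags.get(frozenset((a, b)), False)),
                )
            )
    co = [p for p in pairs if p.same_cluster]
    genes_in_co = {g for p in co for g in (p.gene_a, p.gene_b)}
    genes_in_insulae = sum(i.size for i in insulae)
    summary = {
        "n_adjacent_pairs": len(pairs),
        "n_coexpressed_pairs": len(co),
        "n_genes_in_coexpressed_pairs": len(genes_in_co),
        "pct_insula_genes_coexpressed_with_neighbor": round(
            100.0 * len(genes_in_co) / genes_in_insulae, 1
        )
        if genes_in_insulae
        else 0.0,
        "n_duplicated_coexpressed_pairs": sum(p.duplicated_pair for p in co),
        "pct_duplicated_coexpressed_pairs": round(
            100.0 * sum(p.duplicated_pair for p in co) / len(co), 1
        )
        if co
        else 0.0,
        "mean_intergenic_bp_coexpressed": (
            float(np.mean([p.intergenic_bp for p in co])) if co else float("nan")
        ),
        "n_divergent_coexpressed": sum(1 for p in co if p.orientation == "divergent"),
    }
    return pairs, summary


def coexpression_stats_from_counts(
    n_genes_in_insulae: int,
    n_insulae: int,
    n_genes_coexpressed: int,
    n_coexpressed_pairs: int,
    n_duplicated_pairs: int,
) -> dict:
    """Headline insula/co-expression percentages from summary counts."""
    return {
        "mean_genes_per_insula": round(n_genes_in_insulae / n_insulae, 1),
        "pct_insula_genes_coexpressed_with_neighbor": round(
            100.0 * n_genes_coexpressed / n_genes_in_insulae, 1
        ),
        "pct_duplicated_coexpressed_pairs": round(
            100.0 * n_duplicated_pairs / n_coexpressed_pairs, 1
        ),
    }


def cluster_region_composition(
    clusters: Mapping[str, int],
    positions: Mapping[str, float],
    regions: RegionTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x region contingency table plus, per cluster, a chi-square
    test of homogeneity of that cluster's share across regions
    (df = regions - 1). Tests with expected counts < 1 in more than 20% of
    cells are flagged unreliable."""
    names = regions.names
    ids = sorted(clusters)
    region_of = {lid: assign_region(positions[lid], regions) for lid in ids}
    cluster_ids = sorted(set(clusters.values()))
    table = pd.DataFrame(0, index=cluster_ids, columns=names)
    for lid in ids:
        table.loc[clusters[lid], region_of[lid]] += 1

    totals = table.sum(axis=0)
    tests = []
    for c in cluster_ids:
        in_c = table.loc[c].to_numpy(dtype=float)
        out_c = (totals - table.loc[c]).to_numpy(dtype=float)
        cont = np.vstack([in_c, out_c])
        keep = cont.sum(axis=0) > 0
        cont = cont[:, keep]
        if cont.shape[1] < 2 or cont.sum(axis=1).min() == 0:
            tests.append({"cluster": c, "chi2": np.nan, "df": np.nan,
                          "p": np.nan, "reliable": False})
            continue
        chi2, p, df, expected = stats.chi2_contingency(cont, correction=False)
        reliable = (expected < 1).mean() <= 0.2
        if not reliable:
            log.warning("composition test for cluster %s unreliable "
                        "(expected counts < 1)", c)
        tests.append({"cluster": c, "chi2": float(chi2), "df": int(df),
                      "p": float(p), "reliable": bool(reliable)})
    pct = 100.0 * table.div(totals, axis=1)
    return pct.join(table, lsuffix="_pct"), pd.DataFrame(tests)


def fisher_enrichment(
    query: set[str],
    universe: set[str],
    term_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-term two-sided Fisher exact enrichment of a query gene set, with
    Benjamini-Hochberg adjustment across terms."""
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    terms: dict[str, set[str]] = {}
    for gene, ts in term_map.items():
        if gene in universe:
            for t in ts:
                terms.setdefault(t, set()).add(gene)
    rows = []
    n_query = len(query)
    n_universe = len(universe)
    for term, members in sorted(terms.items()):
        a = len(query & members)
        b = n_query - a
        c = len(members) - a
        d = n_universe - n_query - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if b == 0 and c == 0:
            odds = 1.0  # degenerate margins: no enrichment signal either way
        rows.append({"term": term, "query_hits": a, "term_size": len(members),
                     "odds_ratio": float(odds), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
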
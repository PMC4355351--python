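from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _builders import make_gene, make_tx
from txatlas import coexpression_clusters as cc
from txatlas.models import RegionTable


class TestCriticalPearson:
    def test_reference_value(self):
        assert round(cc.critical_pearson(15, 0.01), 3) == 0.641

    def test_monotone_in_n(self):
        vals = [cc.critical_pearson(n, 0.01) for n in range(5, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_edge_cases(self):
        assert cc.critical_pearson(15, 1.0) == 0.0
        with pytest.raises(ValueError):
            cc.critical_pearson(3, 0.01)


def _profile_frame(groups: dict[str, np.ndarray], n_each: int, noise: float,
                   seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows, idx = [], []
    for name, base in groups.items():
        for i in range(n_each):
            rows.append(base * rng.lognormal(0, noise, len(base)))
            idx.append(f"{name}{i:02d}")
    return pd.DataFrame(rows, index=idx)


class TestClustering:
    def test_two_clean_groups(self):
        a = np.array([10.0] * 8 + [0.1] * 7)
        b = a[::-1].copy()
        frame = _profile_frame({"a": a, "b": b}, 10, 0.05)
        res = cc.cluster_profiles(frame)
        assert res.n_clusters == 2
        labels = {lid[0]: res.assignments[lid] for lid in frame.index}
        assert labels["a"] != labels["b"]

    def test_constant_profiles_reserved_cluster(self):
        frame = pd.DataFrame(
            [[1.0] * 6, [1.0] * 6, np.arange(6.0), np.arange(6.0) * 2],
            index=["c1", "c2", "v1", "v2"],
        )
        res = cc.cluster_profiles(frame)
        assert res.assignments["c1"] == 0 and res.assignments["c2"] == 0
        assert res.assignments["v1"] == res.assignments["v2"] == 1

    def test_order_invariance(self):
        a = np.array([5.0, 1, 5, 1, 5, 1])
        b = np.array([1.0, 5, 1, 5, 1, 5])
        frame = _profile_frame({"a": a, "b": b}, 5, 0.05)
        res1 = cc.cluster_profiles(frame)
        res2 = cc.cluster_profiles(frame.iloc[::-1])
        assert res1.assignments == res2.assignments

    def test_single_active_profile(self):
        frame = pd.DataFrame([np.arange(6.0)], index=["x"])
        assert cc.cluster_profiles(frame).assignments == {"x": 1}

    def test_cut_monotonicity(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.lognormal(0, 1, (40, 15)),
                             index=[f"g{i}" for i in range(40)])
        ks = [cc.cluster_profiles(frame, cut).n_clusters
              for cut in (0.2, 0.4, 0.641, 0.8, 0.95)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))


def _insula_genes():
    # gaps: 500 (in), 40_000 (out), 100 (in), 29_999 (in)
    spans = [(1_000, 2_000), (2_501, 3_000), (43_001, 44_000),
             (44_101, 45_000), (75_000, 76_000)]
    strands = ["+", "-", "+", "+", "-"]
    return [
        make_gene([make_tx([s], f"g{i}.1", f"g{i}")], gene_id=f"g{i}",
                  strand=st)
        for i, (s, st) in enumerate(zip(spans, strands))
    ]


class TestInsulae:
    def test_detection(self):
        ins = cc.detect_insulae(_insula_genes(), 30_000)
        assert [i.members for i in ins] == [["g0", "g1"], ["g2", "g3", "g4"]]
        assert ins[0].internal_gaps == [500]
        assert ins[1].internal_gaps == [100, 29_999]

    def test_singletons_excluded(self):
        ins = cc.detect_insulae(_insula_genes(), 200)
        assert [i.members for i in ins] == [["g2", "g3"]]

    def test_threshold_monotonicity(self):
        genes = _insula_genes()
        sizes = [sum(i.size for i in cc.detect_insulae(genes, t))
                 for t in (50, 200, 1_000, 30_000, 50_000)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_overlapping_genes_clamped(self, caplog):
        g1 = make_gene([make_tx([(100, 500)], "a.1", "a")], gene_id="a")
        g2 = make_gene([make_tx([(400, 900)], "b.1", "b")], gene_id="b")
        with caplog.at_level("WARNING"):
            ins = cc.detect_insulae([g1, g2], 30_000)
        assert ins[0].internal_gaps == [0]
        assert "clamped" in caplog.text

    def test_summary(self):
        ins = cc.detect_insulae(_insula_genes(), 30_000)
        out = cc.insulae_summary(ins, 5)
        assert out["n_insulae"] == 2
        assert out["genes_in_insulae"] == 5
        assert out["pct_genes_in_insulae"] == 100.0
        assert out["mean_genes_per_insula"] == 2.5


class TestPairs:
    def test_orientation(self):
        assert cc.pair_orientation("-", "+") == "divergent"
        assert cc.pair_orientation("+", "-") == "convergent"
        assert cc.pair_orientation("+", "+") == "tandem"
        assert cc.pair_orientation("-", "-") == "tandem"

    def test_coexpressed_pairs_and_chains(self):
        genes = _insula_genes()
        ins = cc.detect_insulae(genes, 30_000)
        clusters = {"g0": 1, "g1": 2, "g2": 3, "g3": 3, "g4": 3}
        dup = {frozenset(("g3", "g4")): True}
        pairs, summary = cc.coexpressed_pairs(ins, clusters, genes, dup)
        assert len(pairs) == 3
        co = [p for p in pairs if p.same_cluster]
        assert {(p.gene_a, p.gene_b) for p in co} == {("g2", "g3"), ("g3", "g4")}
        # the g2-g3-g4 chain has 3 distinct genes, not 4
        assert summary["n_genes_in_coexpressed_pairs"] == 3
        assert summary["pct_insula_genes_coexpressed_with_neighbor"] == 60.0
        assert summary["pct_duplicated_coexpressed_pairs"] == 50.0
        assert summary["n_divergent_coexpressed"] == 0
        ori = {(p.gene_a, p.gene_b): p.orientation for p in pairs}
        assert ori[("g0", "g1")] == "convergent"
        assert ori[("g3", "g4")] == "convergent"
        assert ori[("g2", "g3")] == "tandem"

    def test_stats_from_counts(self):
        out = cc.coexpression_stats_from_counts(29, 10, 11, 8, 2)
        assert out["mean_genes_per_insula"] == 2.9
        assert out["pct_insula_genes_coexpressed_with_neighbor"] == 37.9
        assert out["pct_duplicated_coexpressed_pairs"] == 25.0


class TestComposition:
    def test_enrichment_detected(self):
        regions = RegionTable([("L", 0, 1000), ("R", 1000, 2000)])
        clusters, positions = {}, {}
        for i in range(60):  # cluster 1 only on the left
            clusters[f"a{i}"], positions[f"a{i}"] = 1, 500
        for i in range(60):  # cluster 2 on both sides
            clusters[f"b{i}"], positions[f"b{i}"] = 2, 500 if i < 30 else 1500
        table, tests = cc.cluster_region_composition(clusters, positions, regions)
        t1 = tests.set_index("cluster").loc[1]
        assert t1["p"] < 0.01 and bool(t1["reliable"])
        assert table.loc[1, "R"] == 0

    def test_unreliable_flagged(self, caplog):
        regions = RegionTable([("L", 0, 1000), ("R", 1000, 2000)])
        clusters = {"a": 1, "b": 2, "c": 2}
        positions = {"a": 500, "b": 500, "c": 1500}
        with caplog.at_level("WARNING"):
            _, tests = cc.cluster_region_composition(clusters, positions, regions)
        assert not tests["reliable"].all()


class TestFisher:
    def test_known_table(self):
        from scipy import stats
        # query of 10 with 8 hits vs universe of 20 with 10 term members
        term_map = {f"g{i}": {"T"} for i in list(range(8)) + [10, 11]}
        query = {f"g{i}" for i in range(10)}
        universe = {f"g{i}" for i in range(20)}
        df = cc.fisher_enrichment(query, universe, term_map)
        odds, p = stats.fisher_exact([[8, 2], [2, 8]])
        assert df.loc[0, "odds_ratio"] == pytest.approx(odds)
        assert df.loc[0, "p"] == pytest.approx(p)
        assert df.loc[0, "q"] == pytest.approx(p)  # single term

    def test_degenerate_margins(self):
        universe = {"a", "b", "c", "d"}
        df = cc.fisher_enrichment(universe, universe, {g: {"T"} for g in universe})
        assert df.loc[0, "odds_ratio"] == 1.0
        assert df.loc[0, "p"] == 1.0

    def test_bh_adjustment_order(self):
        term_map = {f"g{i}": {"T1"} for i in range(8)}
        for i in range(20):
            term_map.setdefault(f"g{i}", set()).add("T2")
        query = {f"g{i}" for i in range(8)}
        universe = {f"g{i}" for i in range(20)}
        df = cc.fisher_enrichment(query, universe, term_map).set_index("term")
        assert (df["q"] >= df["p"] - 1e-12).all()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty query"):
            cc.fisher_enrichment(set(), {"a"}, {})
        with pytest.raises(ValueError, match="subset"):
            cc.fisher_enrichment({"x"}, {"a"}, {})


def test_synthetic_clusters_recovered(ts_dataset):
    from sklearn.metrics import adjusted_rand_score
    truth = ts_dataset.truth["loci"]
    ids = sorted(g.gene_id for g in ts_dataset.genes
                 if truth[g.gene_id]["expressed"])
    res = cc.cluster_profiles(ts_dataset.matrix.values.loc[ids])
    ari = adjusted_rand_score([truth[i]["cluster"] for i in ids],
                              [res.assignments[i] for i in ids])
    assert ari >= 0.95
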
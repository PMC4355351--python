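from __future__ import annotations

import pandas as pd
import pytest

from _builders import make_gene, make_matrix, make_tx
from txatlas import tar_classification as tc
from txatlas.models import TAR


def _gene(gid, start, end, strand="+", category="full"):
    return make_gene([make_tx([(start, end)], f"{gid}.1", gid)], gene_id=gid,
                     strand=strand, category=category)


class TestCallTars:
    def _setup(self):
        genes = [_gene("A", 100, 500), _gene("B", 1000, 1400, category="pseudogene_fragment")]
        matrix = make_matrix({"A": [1.0, 0, 0], "B": [0, 0, 0], "N1": [0, 2.0, 0]},
                             columns=["leaf:1", "leaf:2", "root:1"])
        return genes, matrix, {"N1": (2000, 2300)}

    def test_classes_and_omission(self):
        genes, matrix, ntr = self._setup()
        tars = tc.call_tars(genes, matrix, ntr)
        by_id = {t.tar_id: t for t in tars}
        assert by_id["A"].tar_class == "gene_full"
        assert "B" not in by_id  # not expressed anywhere -> no TAR
        assert by_id["N1"].tar_class == "NTR"
        assert by_id["N1"].strand == "."
        assert by_id["A"].expressed_conditions == ["leaf:1"]

    def test_pseudo_class(self):
        genes, matrix, ntr = self._setup()
        matrix.values.loc["B", "root:1"] = 3.0
        tars = tc.call_tars(genes, matrix, ntr)
        assert {t.tar_id: t.tar_class for t in tars}["B"] == "gene_pseudo"

    def test_fpkm_floor(self):
        genes, matrix, ntr = self._setup()
        tars = tc.call_tars(genes, matrix, ntr, fpkm_floor=1.5)
        assert {t.tar_id for t in tars} == {"N1"}

    def test_orphan_row_error(self):
        genes, matrix, _ = self._setup()
        with pytest.raises(ValueError, match="without annotation"):
            tc.call_tars(genes, matrix, {})

    def test_ntr_overlapping_gene_error(self):
        genes, matrix, _ = self._setup()
        with pytest.raises(ValueError, match="overlaps an annotated gene"):
            tc.call_tars(genes, matrix, {"N1": (400, 600)})


class TestLongestORF:
    def test_basic(self):
        assert tc.find_longest_orf("ATGAAATAG") == 2

    def test_orf_needs_stop(self):
        assert tc.find_longest_orf("ATGAAAAAA") == 0

    def test_reverse_strand(self):
        # reverse complement of ATGAAATAG
        assert tc.find_longest_orf("CTATTTCAT") == 2

    def test_frames(self):
        assert tc.find_longest_orf("CCATGAAATAG") == 2  # frame 2

    def test_empty(self):
        assert tc.find_longest_orf("") == 0

    def test_longest_of_several(self):
        # the initiator Met counts, the stop does not: ATG + 10 codons = 11
        seq = "ATGAAATAG" + "ATG" + "GCT" * 10 + "TGA"
        assert tc.find_longest_orf(seq) == 11


class TestLincRNA:
    def _ntr(self, nid="N1"):
        return TAR(nid, "chr1", 1, 500, ".", "NTR", None, ["leaf:1"])

    def test_length_filter_is_strict(self):
        for n, expected in ((200, False), (201, True)):
            calls = tc.classify_lincRNAs([self._ntr()], {"N1": "AC" * (n // 2) + "A" * (n % 2)}, {})
            assert calls[0].is_lincRNA is expected, n

    def test_orf_bound_inclusive(self):
        # ORF of exactly max_orf_aa passes; one more fails
        def seq_with_orf(aa):  # ATG counts toward the ORF length
            return "ATG" + "GCT" * (aa - 1) + "TAA" + "C" * 250
        ok = tc.classify_lincRNAs([self._ntr()], {"N1": seq_with_orf(300)}, {})
        bad = tc.classify_lincRNAs([self._ntr()], {"N1": seq_with_orf(301)}, {})
        assert ok[0].is_lincRNA and not bad[0].is_lincRNA

    def test_protein_similarity_excludes(self):
        calls = tc.classify_lincRNAs([self._ntr()], {"N1": "AC" * 200}, {"N1": True})
        assert not calls[0].is_lincRNA

    def test_missing_sequence_uncallable(self, caplog):
        with caplog.at_level("WARNING"):
            calls = tc.classify_lincRNAs([self._ntr()], {}, {})
        assert calls[0].uncallable and not calls[0].is_lincRNA
        assert "uncallable" in caplog.text


class TestCisNat:
    def _anti(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])

    def test_opposite_strand_only(self):
        g = _gene("A", 100, 500, strand="+")
        anti = self._anti([("chr1", 200, 300, "-"), ("chr1", 200, 300, "+")])
        calls = tc.detect_cis_nats([g], anti, {"A"})
        assert calls[0].is_cis_nat and calls[0].antisense_overlap_bp == 101

    def test_not_expressed_not_called(self):
        g = _gene("A", 100, 500)
        anti = self._anti([("chr1", 100, 500, "-")])
        assert not tc.detect_cis_nats([g], anti, set())[0].is_cis_nat

    def test_min_overlap_threshold(self):
        g = _gene("A", 100, 500)
        anti = self._anti([("chr1", 490, 520, "-")])  # 11 bp overlap
        assert tc.detect_cis_nats([g], anti, {"A"}, min_overlap_bp=11)[0].is_cis_nat
        assert not tc.detect_cis_nats([g], anti, {"A"}, min_overlap_bp=12)[0].is_cis_nat

    def test_unknown_chrom_error(self):
        g = _gene("A", 100, 500)
        anti = self._anti([("chrX", 1, 10, "-")])
        with pytest.raises(ValueError, match="unknown chromosome"):
            tc.detect_cis_nats([g], anti, {"A"})


class TestSyntheticRecovery:
    def test_classes_match_truth(self, ts_dataset):
        tars = tc.call_tars(ts_dataset.genes, ts_dataset.matrix,
                            ts_dataset.ntr_intervals)
        truth = ts_dataset.truth["loci"]
        for t in tars:
            tl = truth[t.tar_id]
            assert tl["expressed"]
            expected = {"full": "gene_full", "pseudogene": "gene_pseudo"}.get(
                tl["class"], "NTR")
            assert t.tar_class == expected
        called = {t.tar_id for t in tars}
        for lid, tl in truth.items():
            assert (lid in called) == bool(tl["expressed"])

    def test_lincrna_calls_match_truth(self, ts_dataset):
        tars = tc.call_tars(ts_dataset.genes, ts_dataset.matrix,
                            ts_dataset.ntr_intervals)
        ntrs = [t for t in tars if t.tar_class == "NTR"]
        calls = tc.classify_lincRNAs(ntrs, ts_dataset.sequences,
                                     ts_dataset.similarity_flags)
        truth = ts_dataset.truth["loci"]
        for c in calls:
            assert c.is_lincRNA == truth[c.tar_id]["is_lincRNA"], c

    def test_cis_nat_calls_match_truth(self, ts_dataset):
        truth = ts_dataset.truth["loci"]
        expressed = {g.gene_id for g in ts_dataset.genes
                     if truth[g.gene_id]["expressed"]}
        calls = tc.detect_cis_nats(ts_dataset.genes, ts_dataset.antisense, expressed)
        for c in calls:
            assert c.is_cis_nat == truth[c.gene_id]["is_cis_nat"], c


class TestSummaries:
    def test_summary_from_counts_basic(self):
        out = tc.summary_from_counts(100, 50, 60, 20, 30, chrom_length_bp=11_000_000)
        assert out["predicted_genes"] == 150
        assert out["expressed_genes"] == 80
        assert out["n_tars"] == 110
        assert out["pct_gene_models_expressed"] == round(100 * 80 / 150, 1)
        assert out["pct_pseudo_expressed"] == 40.0
        assert out["mean_tar_spacing_kb"] == 100.0
        assert out["pct_ntr_of_tars"] == round(100 * 30 / 110, 1)

    def test_summarize_tars_counts(self, ts_dataset):
        tars = tc.call_tars(ts_dataset.genes, ts_dataset.matrix,
                            ts_dataset.ntr_intervals)
        out = tc.summarize_tars(tars, ts_dataset.genes)
        assert out["n_tars"] == len(tars)
        assert out["predicted_genes"] == len(ts_dataset.genes)
        table = tc.tars_to_table(tars)
        assert len(table) == len(tars)
        assert set(table["class"]) <= {"gene_full", "gene_pseudo", "NTR"}
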
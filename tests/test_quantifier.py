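import numpy as np
import pytest
import scipy.sparse as sp
from Bio.Seq import reverse_complement

import cd45iso as c
from cd45iso.bam_reads import ReadRecord
from cd45iso.quantifier import Assignment, CountMatrix

FEATURES = ["RA", "RB", "RC", "RO"]


def assign(barcode, umi, features, qname="q"):
    return Assignment(qname=qname, barcode=barcode, umi=umi, features=frozenset(features))


class TestBuildIndex:
    def test_kmer_position_count(self, rng):
        from conftest import model_from_seqs, random_seq
        from cd45iso.reference_builder import FlankedTranscript, ReferenceSet

        seq = random_seq(194, rng)
        refset = ReferenceSet(
            transcripts=(
                FlankedTranscript("RO|a|b", "RO", (), (), seq, 97, 97),
            ),
            read_len=98,
            min_overlap=1,
        )
        index = c.build_index(refset, k=31)
        # random 31-mers essentially never repeat within 194 bases
        assert len(index.kmer_map) == 194 - 31 + 1

    def test_shared_kmer_maps_to_both_refs(self, index, refset):
        shared = [
            hits
            for hits in index.kmer_map.values()
            if len({ref_id for ref_id, _pos in hits}) > 1
        ]
        assert shared, "flank sharing must produce multi-reference k-mers"

    def test_k_larger_than_reference_rejected(self, refset):
        with pytest.raises(ValueError, match="exceeds"):
            c.build_index(refset, k=10_000)

    def test_small_k_rejected(self, refset):
        with pytest.raises(ValueError, match=">= 11"):
            c.build_index(refset, k=5)


class TestClassifyRead:
    def test_read_inside_alternative_exon(self, toy_model, index):
        e4 = toy_model.exons[3].sequence
        assert c.classify_read(e4[:98], index) == {"RA"}

    def test_read_spanning_two_alternative_exons(self, toy_model, index):
        e4, e5 = toy_model.exons[3].sequence, toy_model.exons[4].sequence
        read = e4[-49:] + e5[:49]
        assert c.classify_read(read, index) == {"RA", "RB"}

    def test_junction_read_hits_skip_isoform_only(self, toy_model, index):
        e3, e7 = toy_model.exons[2].sequence, toy_model.exons[6].sequence
        assert c.classify_read(e3[-49:] + e7[:49], index) == {"RO"}

    def test_reverse_complement_read_classified_identically(self, toy_model, index):
        e4 = toy_model.exons[3].sequence
        assert c.classify_read(reverse_complement(e4[:98]), index) == {"RA"}

    def test_unrelated_sequence_unassigned(self, index, rng):
        from conftest import random_seq

        assert c.classify_read(random_seq(98, rng), index) == frozenset()

    def test_read_shorter_than_k_unassigned(self, index):
        assert c.classify_read("ACGT", index) == frozenset()


class TestClassifyGenomic:
    def _record(self, toy_model, pos, cigar):
        length = sum(l for op, l in cigar if op in (0, 1, 4, 7, 8))
        return ReadRecord(
            qname="q",
            barcode="BC",
            umi="U",
            sequence="A" * length,
            chrom=toy_model.chrom,
            pos=pos,
            cigar=cigar,
            mapq=255,
        )

    def test_contiguous_read_inside_exon(self, toy_model, rules):
        e4 = toy_model.exons[3]
        rec = self._record(toy_model, e4.start0, ((0, 98),))
        assert c.classify_read_genomic(rec, toy_model, rules, k=1) == {"RA"}

    def test_gap_bridging_junction(self, toy_model, rules):
        e3, e7 = toy_model.exons[2], toy_model.exons[6]
        gap = e7.start0 - e3.end0
        rec = self._record(toy_model, e3.end0 - 49, ((0, 49), (3, gap), (0, 49)))
        assert c.classify_read_genomic(rec, toy_model, rules, k=1) == {"RO"}

    def test_gap_not_at_exon_boundaries_is_not_a_junction(self, toy_model, rules):
        e3, e7 = toy_model.exons[2], toy_model.exons[6]
        gap = e7.start0 - e3.end0
        rec = self._record(toy_model, e3.end0 - 50, ((0, 49), (3, gap), (0, 49)))
        assert c.classify_read_genomic(rec, toy_model, rules, k=1) == frozenset()

    def test_overlap_below_threshold_not_reported(self, toy_model, rules):
        e4 = toy_model.exons[3]
        k = 10
        rec = self._record(toy_model, e4.start0 - 98 + (k - 1), ((0, 98),))
        feats = c.classify_read_genomic(rec, toy_model, rules, k=k)
        assert "RA" not in feats
        rec2 = self._record(toy_model, e4.start0 - 98 + k, ((0, 98),))
        assert "RA" in c.classify_read_genomic(rec2, toy_model, rules, k=k)


class TestQuantify:
    def test_umi_deduplication(self):
        assignments = [assign("BC1", "U1", {"RA"}, qname=f"q{i}") for i in range(3)]
        m = c.quantify(assignments, FEATURES, whitelist=["BC1"])
        assert m.feature_vector("RA")[0] == 1.0
        assert m.total() == 1.0

    def test_multifeature_weight_split(self):
        m = c.quantify([assign("BC1", "U1", {"RA", "RB"})], FEATURES, whitelist=["BC1"])
        assert m.feature_vector("RA")[0] == 0.5
        assert m.feature_vector("RB")[0] == 0.5

    def test_distinct_umis_count_separately(self):
        assignments = [assign("BC1", "U1", {"RA"}), assign("BC1", "U2", {"RO"})]
        m = c.quantify(assignments, FEATURES, whitelist=["BC1"])
        assert m.feature_vector("RA")[0] == 1.0
        assert m.feature_vector("RO")[0] == 1.0

    def test_unassigned_groups_contribute_nothing(self):
        m = c.quantify([assign("BC1", "U1", set())], FEATURES, whitelist=["BC1"])
        assert m.total() == 0.0

    def test_whitelist_barcodes_all_present_even_if_zero(self):
        m = c.quantify([assign("BC1", "U1", {"RA"})], FEATURES, whitelist=["BC1", "BC2"])
        assert m.barcodes == ["BC1", "BC2"]
        assert m.feature_vector("RA").tolist() == [1.0, 0.0]

    def test_forced_cells_keeps_top_barcodes(self):
        assignments = [
            assign(f"BC{i}", f"U{j}", {"RA"}) for i in range(5) for j in range(i + 1)
        ]
        m = c.quantify(assignments, FEATURES, forced_cells=2)
        assert m.barcodes == ["BC4", "BC3"]

    def test_weight_conservation(self, rng):
        labels = [frozenset(s) for s in ({"RA"}, {"RB", "RO"}, {"RA", "RB", "RC"}, set())]
        assignments = [
            assign(f"BC{rng.integers(4)}", f"U{i}", labels[rng.integers(len(labels))])
            for i in range(200)
        ]
        m = c.quantify(assignments, FEATURES, whitelist=[f"BC{i}" for i in range(4)])
        n_assigned = len({(a.barcode, a.umi) for a in assignments if a.features})
        assert m.total() == pytest.approx(n_assigned)

    def test_umi_group_unions_features_across_reads(self):
        assignments = [assign("BC1", "U1", {"RA"}), assign("BC1", "U1", {"RO"})]
        m = c.quantify(assignments, FEATURES, whitelist=["BC1"])
        assert m.feature_vector("RA")[0] == 0.5
        assert m.feature_vector("RO")[0] == 0.5


class TestMergeAndNormalize:
    def _matrix(self, barcodes, data):
        return CountMatrix(FEATURES, barcodes, np.asarray(data, dtype=float))

    def test_disjoint_barcodes_concatenate(self):
        a = self._matrix(["A"], [[1.0], [0], [0], [0]])
        b = self._matrix(["B"], [[0], [2.0], [0], [0]])
        merged = c.merge_counts(a, b)
        assert merged.barcodes == ["A", "B"]
        assert merged.feature_vector("RA").tolist() == [1.0, 0.0]

    def test_shared_barcode_sums(self):
        a = self._matrix(["A"], [[1.0], [0], [0], [0]])
        b = self._matrix(["A"], [[2.0], [0], [0], [0]])
        assert c.merge_counts(a, b).feature_vector("RA")[0] == 3.0

    def test_empty_right_operand_is_identity(self):
        a = self._matrix(["A", "B"], [[1.0, 2.0], [0, 0], [0, 0], [0, 0.5]])
        b = CountMatrix(FEATURES, [], sp.csr_matrix((4, 0)))
        merged = c.merge_counts(a, b)
        assert np.allclose(merged.to_dense(), a.to_dense())

    def test_feature_mismatch_rejected(self):
        a = self._matrix(["A"], [[0], [0], [0], [0]])
        b = CountMatrix(["RA"], ["A"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="different features"):
            c.merge_counts(a, b)

    def test_merge_is_commutative_on_totals(self, rng):
        a = self._matrix(["A", "B"], rng.random((4, 2)))
        b = self._matrix(["B", "C"], rng.random((4, 2)))
        ab, ba = c.merge_counts(a, b), c.merge_counts(b, a)
        for bc in ["A", "B", "C"]:
            ia, ib = ab.barcodes.index(bc), ba.barcodes.index(bc)
            assert np.allclose(ab.to_dense()[:, ia], ba.to_dense()[:, ib])

    def test_log_normalize_single_feature_cell(self):
        m = self._matrix(["A"], [[5.0], [0], [0], [0]])
        out = c.log_normalize(m, scale=10_000)
        assert out[0, 0] == pytest.approx(np.log2(1 + 10_000))

    def test_log_normalize_zero_cell_stays_zero(self):
        m = self._matrix(["A"], np.zeros((4, 1)))
        assert np.all(c.log_normalize(m) == 0.0)

    def test_log_normalize_fractional_total(self):
        m = self._matrix(["A"], [[10.0], [90.0], [0], [0]])
        out = c.log_normalize(m, scale=10_000)
        assert out[0, 0] == pytest.approx(np.log2(1001), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            self._matrix(["A"], [[-1.0], [0], [0], [0]])


class TestOracleEquivalence:
    def test_kmer_and_genomic_classifiers_agree_on_simulated_reads(
        self, toy_model, rules, index, simulated
    ):
        disagreements = [
            r.qname
            for r in simulated["records"]
            if c.classify_read(r.sequence, index, min_kmer_frac=1.0)
            != c.classify_read_genomic(r, toy_model, rules, k=1)
        ]
        assert disagreements == []

    def test_truth_recovery_end_to_end(self, toy_model, rules, simulated):
        truth = simulated["truth"]
        m = c.quantify_records(
            simulated["records"],
            toy_model,
            rules,
            min_kmer_frac=1.0,
            whitelist=truth.barcodes,
        )
        expected = truth.expected_counts(list(rules.feature_names))
        assert np.allclose(m.to_dense(), expected.values)
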
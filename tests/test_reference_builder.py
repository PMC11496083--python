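import numpy as np
import pytest

import cd45iso as c
from cd45iso.reference_builder import FeatureSpec, FlankedTranscript

from conftest import model_from_seqs, random_seq


def scan_windows(transcript, read_len, min_overlap):
    """Count length-R windows whose feature overlap falls below min_overlap."""
    violations = 0
    fs, fe = transcript.feature_start, transcript.feature_end
    for s in range(len(transcript.sequence) - read_len + 1):
        w0, w1 = s, s + read_len
        if fs == fe:  # junction: needs min_overlap aligned bases on both sides
            ok = (fs - w0) >= min_overlap and (w1 - fs) >= min_overlap
        else:
            ok = min(w1, fe) - max(w0, fs) >= min_overlap
        violations += not ok
    return violations


class TestFlankLength:
    @pytest.mark.parametrize("read_len,k,expected", [(98, 1, 97), (91, 5, 86), (50, 25, 25)])
    def test_flank_is_read_len_minus_overlap(self, read_len, k, expected):
        assert c.compute_flank_length(read_len, k) == expected

    def test_read_too_short_for_junction_overlap(self):
        with pytest.raises(ValueError, match="too short"):
            c.compute_flank_length(8, 5)

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="min_overlap"):
            c.compute_flank_length(98, 0)


class TestParseRules:
    def test_features_and_follows(self, tmp_path, toy_model):
        p = tmp_path / "rules.txt"
        p.write_text(
            "# CD45-style rules\n"
            "feature RA exon E4\n"
            "feature RO junction E3 E7\n"
            "follows E3: E4,E5,E6,E7\n"
        )
        rules = c.parse_rules(p, toy_model)
        assert rules.feature_names == ("RA", "RO")
        assert rules.follows["E3"] == ("E4", "E5", "E6", "E7")

    def test_upstream_follows_edge_rejected(self, tmp_path, toy_model):
        p = tmp_path / "rules.txt"
        p.write_text("feature RA exon E4\nfollows E5: E4\n")
        with pytest.raises(ValueError, match="transcript order"):
            c.parse_rules(p, toy_model)

    def test_unknown_exon_rejected(self, tmp_path, toy_model):
        p = tmp_path / "rules.txt"
        p.write_text("feature RA exon E99\n")
        with pytest.raises(ValueError, match="unknown exon"):
            c.parse_rules(p, toy_model)

    def test_junction_with_reversed_exons_rejected(self, tmp_path, toy_model):
        p = tmp_path / "rules.txt"
        p.write_text("feature RO junction E7 E3\n")
        with pytest.raises(ValueError, match="transcript order"):
            c.parse_rules(p, toy_model)


class TestEnumerateChains:
    def _model(self, rng, lens):
        return model_from_seqs([random_seq(n, rng) for n in lens])

    def test_long_first_exons_terminate_chains(self, rng):
        # E4 -> {E5, E7}, E5 -> {E7}; every exon 200 bp >= flank 97
        model = self._model(rng, [200] * 7)
        rules = c.BuildRules(
            features=(FeatureSpec("RA", "exon", "E4"),),
            follows={"E4": ("E5", "E7"), "E5": ("E7",)},
        )
        chains = c.enumerate_flank_chains(rules, model, "E4", "downstream", 97)
        assert sorted(chains) == [("E5",), ("E7",)]

    def test_short_exon_extends_chain(self, rng):
        model = self._model(rng, [200, 200, 200, 200, 40, 200, 200])
        rules = c.BuildRules(
            features=(FeatureSpec("RA", "exon", "E4"),),
            follows={"E4": ("E5", "E7"), "E5": ("E7",)},
        )
        chains = c.enumerate_flank_chains(rules, model, "E4", "downstream", 97)
        assert sorted(chains) == [("E5", "E7"), ("E7",)]

    def test_terminal_anchor_yields_single_empty_chain(self, rng, toy_model):
        rules = c.default_ptprc_rules(toy_model)
        last = toy_model.exon_ids[-1]
        assert c.enumerate_flank_chains(rules, toy_model, last, "downstream", 97) == [()]


class TestBuildReference:
    def test_junction_reference_geometry(self, rng):
        model = self._junction_model(rng)
        rules = c.BuildRules(
            features=(FeatureSpec("RO", "junction", ("E3", "E7")),),
            follows={"E3": ("E7",)},
        )
        refset = c.build_reference(model, rules, read_len=98, min_overlap=1)
        assert len(refset.transcripts) == 1
        t = refset.transcripts[0]
        assert len(t.sequence) == 194
        assert (t.feature_start, t.feature_end) == (97, 97)

    @staticmethod
    def _junction_model(rng):
        return model_from_seqs([random_seq(150, rng) for _ in range(7)])

    def test_exon_reference_count_and_length(self, rng):
        seqs = [random_seq(n, rng) for n in [150, 150, 150, 150, 150, 150, 150]]
        model = model_from_seqs(seqs)
        rules = c.BuildRules(
            features=(FeatureSpec("RA", "exon", "E4"),),
            follows={"E3": ("E4",), "E4": ("E5", "E7"), "E5": ("E7",)},
        )
        refset = c.build_reference(model, rules, read_len=98, min_overlap=1)
        assert len(refset.transcripts) == 2  # one upstream x two downstream chains
        assert {len(t.sequence) for t in refset.transcripts} == {97 + 150 + 97}

    def test_containment_guarantee_on_toy_model(self, refset):
        total = sum(
            scan_windows(t, refset.read_len, refset.min_overlap)
            for t in refset.transcripts
        )
        assert total == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_containment_guarantee_on_randomized_models(self, seed):
        rng = np.random.default_rng(seed)
        read_len = int(rng.integers(50, 151))
        k = int(rng.integers(1, min(11, read_len // 2 + 1)))
        model, _ = c.synthetic.make_toy_model(
            n_exons=int(rng.integers(7, 12)), seed=seed + 50
        )
        refset = c.build_reference(model, c.default_ptprc_rules(model), read_len, k)
        assert all(scan_windows(t, read_len, k) == 0 for t in refset.transcripts)

    def test_feature_map_covers_all_transcripts(self, refset):
        assert set(refset.feature_map.values()) == set(refset.feature_names)
        assert len(refset.feature_map) == len(refset.transcripts)

    def test_exon_shorter_than_overlap_rejected(self, rng):
        seqs = [random_seq(150, rng) for _ in range(7)]
        seqs[3] = random_seq(3, rng)
        model = model_from_seqs(seqs)
        rules = c.BuildRules(
            features=(FeatureSpec("RA", "exon", "E4"),),
            follows={"E3": ("E4",), "E4": ("E5",)},
        )
        with pytest.raises(ValueError, match="shorter than"):
            c.build_reference(model, rules, read_len=98, min_overlap=5)


class TestDefaultRules:
    def test_human_scale_model_yields_four_features(self):
        model, _ = c.synthetic.make_toy_model(n_exons=33, seed=0)
        rules = c.default_ptprc_rules(model)
        assert rules.feature_names == ("RA", "RB", "RC", "RO")
        assert rules.follows["E3"] == ("E4", "E5", "E6", "E7")

    def test_short_model_rejected(self, rng):
        model = model_from_seqs([random_seq(100, rng) for _ in range(6)])
        with pytest.raises(ValueError, match="too short"):
            c.default_ptprc_rules(model)


class TestWriteReference:
    def test_fasta_and_t2g_row_counts(self, refset, tmp_path):
        fasta, t2g = tmp_path / "ref.fa", tmp_path / "t2g.tsv"
        c.write_reference(refset, fasta, t2g)
        n_records = fasta.read_text().count(">")
        assert n_records == len(refset.transcripts)
        rows = [l.split("\t") for l in t2g.read_text().splitlines()]
        assert len(rows) == len(refset.transcripts)
        assert {r[1] for r in rows} == set(refset.feature_names)

    def test_outputs_are_deterministic(self, toy_model, rules, tmp_path):
        payloads = []
        for i in range(2):
            refset = c.build_reference(toy_model, rules, 98, 1)
            fasta, t2g = tmp_path / f"r{i}.fa", tmp_path / f"r{i}.tsv"
            c.write_reference(refset, fasta, t2g)
            payloads.append(fasta.read_bytes() + t2g.read_bytes())
        assert payloads[0] == payloads[1]

    def test_empty_refset_rejected(self):
        refset = c.ReferenceSet(transcripts=(), read_len=98, min_overlap=1)
        with pytest.raises(ValueError, match="empty"):
            c.write_reference(refset, "ref.fa", "t2g.tsv")

    def test_ref_id_with_whitespace_rejected(self):
        with pytest.raises(ValueError, match="whitespace"):
            FlankedTranscript(
                ref_id="bad id",
                feature_name="RA",
                upstream_chain=(),
                downstream_chain=(),
                sequence="ACGT",
                feature_start=0,
                feature_end=4,
            )
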
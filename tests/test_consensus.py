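"""Redundancy filtering, consensus derivation, motif rendering and scanning."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import regex_motif_oracle
from e2face.consensus import (
    AlignmentRecord,
    LabelledAlignment,
    PositionSpec,
    ConsensusMotif,
    classify_sequences,
    derive_consensus,
    map_reference_positions,
    match_motif,
    motif_to_string,
    pairwise_identity,
    parse_motif,
    profile_columns,
    read_alignment,
    redundancy_filter,
)
from e2face.synthetic import simulate_family


def _aln(rows, reference_id=None):
    records = [AlignmentRecord(i, s, l) for i, s, l in rows]
    return LabelledAlignment(records=records, reference_id=reference_id or rows[0][0])


class TestReadAlignment:
    def _write_fixture(self, tmp_path):
        rows = [("ref", "MEEPFK", "high"), ("s2", "MDAPYK", "high"), ("s3", "MKKKKK", "low")]
        fasta = tmp_path / "aln.afa"
        fasta.write_text("".join(f">{i}\n{s}\n" for i, s, _ in rows))
        labels = tmp_path / "labels.tsv"
        labels.write_text("".join(f"{i}\t{l}\n" for i, s, l in rows))
        return rows, fasta, labels

    def test_fasta_and_clustal_give_identical_alignments(self, tmp_path):
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        rows, fasta, labels = self._write_fixture(tmp_path)
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=i, description="") for i, s, _ in rows]
        )
        clustal = tmp_path / "aln.clustal"
        AlignIO.write(msa, str(clustal), "clustal")
        a = read_alignment(fasta, labels, "ref", format="fasta_aligned")
        b = read_alignment(clustal, labels, "ref", format="clustal")
        assert [(r.id, r.seq, r.label) for r in a.records] == [
            (r.id, r.seq, r.label) for r in b.records
        ]

    def test_missing_label_errors(self, tmp_path):
        rows, fasta, labels = self._write_fixture(tmp_path)
        labels.write_text("ref\thigh\ns2\thigh\n")  # s3 unlabelled
        with pytest.raises(ValueError, match="no label"):
            read_alignment(fasta, labels, "ref")

    def test_length_mismatch_and_missing_reference_error(self):
        with pytest.raises(ValueError, match="length"):
            _aln([("a", "ABC", "high"), ("b", "ABCD", "high")])
        with pytest.raises(ValueError, match="reference"):
            _aln([("a", "ABC", "high")], reference_id="zz")
        with pytest.raises(ValueError, match="high"):
            _aln([("a", "ABC", "low")])


class TestPairwiseIdentity:
    def test_identical_ungapped(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 1.0

    def test_gap_gap_column_excluded(self):
        assert pairwise_identity("AC-G", "AC-T") == pytest.approx(2 / 3)

    def test_gap_vs_residue_is_mismatch(self):
        assert pairwise_identity("A-CG", "AACG") == pytest.approx(3 / 4)

    def test_disjoint_is_zero(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("AB", "ABC")

    @given(st.text(alphabet="ACDG-", min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, s):
        import random

        rng = random.Random(hash(s) & 0xFFFF)
        other = "".join(rng.choice("ACDG-") for _ in s)
        a = pairwise_identity(s, other)
        assert a == pairwise_identity(other, s)
        assert 0.0 <= a <= 1.0


class TestRedundancyFilter:
    def test_identical_duplicate_removed(self):
        aln = _aln([("ref", "ACDEF", "high"), ("dup", "ACDEF", "high")])
        kept, log = redundancy_filter(aln)
        assert [r.id for r in kept] == ["ref"]
        assert log[0].removed_id == "dup" and log[0].kept_id == "ref"

    def test_threshold_is_strict(self):
        # 100 columns: 61 matches -> 0.61 removed; 59 matches -> kept
        base = "A" * 100
        s61 = "A" * 61 + "C" * 39
        s59 = "A" * 59 + "C" * 41
        aln = _aln([
            ("ref", base, "high"), ("near", s61, "high"), ("far", s59, "high"),
        ])
        kept, log = redundancy_filter(aln, identity_threshold=0.60)
        assert [r.id for r in kept] == ["ref", "far"]
        assert [e.removed_id for e in log] == ["near"]

    def test_reference_always_kept_even_if_late(self):
        aln = _aln(
            [("a", "ACDEF", "high"), ("ref", "ACDEF", "high")], reference_id="ref"
        )
        kept, log = redundancy_filter(aln)
        assert [r.id for r in kept] == ["ref"]
        assert log[0].removed_id == "a"

    def test_kept_set_pairwise_contract(self, ref_alignment):
        kept, _ = redundancy_filter(ref_alignment, 0.60)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert pairwise_identity(a.seq, b.seq) <= 0.60

    def test_forced_duplicates_from_generator_removed(self):
        records, labels, truth = simulate_family(
            seed=21, identity_pairs=[("HIGH_02", 0.95)]
        )
        aln = LabelledAlignment(
            [AlignmentRecord(i, s, labels[i]) for i, s in records], "HIGH_01"
        )
        kept, log = redundancy_filter(aln, 0.60)
        assert [e.removed_id for e in log] == ["HIGH_02_dup1"]


class TestMapReferencePositions:
    def test_ungapped_reference_offsets(self):
        aln = _aln([("ref", "A" * 70, "high")])
        assert map_reference_positions(aln, 60, 65) == list(range(59, 65))

    def test_gap_before_span_shifts_columns(self):
        ref = "AB-CDEFG"
        aln = _aln([("ref", ref, "high"), ("o", "ABXCDEFG", "high")])
        assert map_reference_positions(aln, 3, 5) == [3, 4, 5]

    def test_span_out_of_range_errors(self):
        aln = _aln([("ref", "ABCDE", "high")])
        with pytest.raises(ValueError, match="span"):
            map_reference_positions(aln, 4, 9)


class TestDeriveConsensus:
    def _records(self, columns_by_record):
        return [
            AlignmentRecord(f"h{i}", seq, "high")
            for i, seq in enumerate(columns_by_record)
        ]

    def test_unanimous_column_is_fixed(self):
        recs = self._records(["P", "P", "P", "P"])
        motif = derive_consensus(recs, [0])
        assert motif.positions[0] == PositionSpec("fixed", ("P",))

    def test_single_class_split_becomes_class_set(self):
        recs = self._records(["D", "E", "D", "E"])
        motif = derive_consensus(recs, [0])
        assert motif.positions[0] == PositionSpec("class", ("D", "E"))

    def test_multi_class_column_is_wildcard(self):
        recs = self._records(["D", "K", "S"])
        motif = derive_consensus(recs, [0])
        assert motif.positions[0].kind == "wildcard"

    def test_gappy_column_is_wildcard(self):
        recs = self._records(["-", "-", "P", "P"])
        motif = derive_consensus(recs, [0])
        assert motif.positions[0].kind == "wildcard"

    def test_low_group_filter_demotes_shared_positions(self):
        recs = self._records(["P", "P", "P"]) + [
            AlignmentRecord(f"l{i}", "P", "low") for i in range(3)
        ]
        keep = derive_consensus(recs, [0], use_low_group_filter=False)
        assert keep.positions[0].kind == "fixed"
        demoted = derive_consensus(recs, [0], use_low_group_filter=True, tau_low=0.5)
        assert demoted.positions[0].kind == "wildcard"

    def test_record_order_invariance(self, ref_alignment):
        kept, _ = redundancy_filter(ref_alignment)
        cols = map_reference_positions(
            dataclasses.replace(ref_alignment, records=kept), 60, 65
        )
        motif_fwd = derive_consensus(kept, cols)
        motif_rev = derive_consensus(list(reversed(kept)), cols)
        assert motif_to_string(motif_fwd) == motif_to_string(motif_rev)

    def test_too_few_high_records_error(self):
        recs = self._records(["P"])
        with pytest.raises(ValueError, match="high-group"):
            derive_consensus(recs, [0])
        with pytest.raises(ValueError, match="column"):
            derive_consensus(self._records(["P", "P"]), [])


class TestMotifStrings:
    def test_paper_style_rendering(self):
        motif = ConsensusMotif(positions=[
            PositionSpec("class", ("D", "E")),
            PositionSpec("wildcard"),
            PositionSpec("fixed", ("P",)),
            PositionSpec("class", ("F", "Y")),
            PositionSpec("fixed", ("K",)),
            PositionSpec("fixed", ("P",)),
        ])
        assert motif_to_string(motif) == "[D/E]xP[F/Y]KP"

    def test_empty_motif_renders_empty(self):
        assert motif_to_string(ConsensusMotif(positions=[])) == ""

    @given(st.lists(
        st.one_of(
            st.sampled_from("ACDEFGHIKLMNPQRSTVWY").map(
                lambda aa: PositionSpec("fixed", (aa,))),
            st.sets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=2, max_size=4).map(
                lambda s: PositionSpec("class", tuple(sorted(s)))),
            st.just(PositionSpec("wildcard")),
        ),
        max_size=8,
    ))
    @settings(max_examples=150, deadline=None)
    def test_round_trip_is_identity(self, positions):
        motif = ConsensusMotif(positions=positions)
        back = parse_motif(motif_to_string(motif))
        assert back.positions == motif.positions


class TestMatchMotif:
    PAPER_MOTIF = parse_motif("[D/E]xP[F/Y]KP")

    def test_reference_window_matches(self):
        # residues 60-65 of the reference E2 sequence
        assert match_motif("EYPFKP", self.PAPER_MOTIF) == [1]

    def test_non_binder_window_rejected(self):
        # corresponding window of a low-activity E2: M at motif position 4,
        # A at position 5
        assert match_motif("EYPMAA", self.PAPER_MOTIF) == []

    def test_short_sequence_empty(self):
        assert match_motif("EYP", self.PAPER_MOTIF) == []

    def test_overlapping_matches_found(self):
        motif = parse_motif("AxA")
        assert match_motif("AAAAA", motif) == [1, 2, 3]

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_equals_regex_oracle(self, data):
        seq = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40))
        positions = data.draw(st.lists(
            st.one_of(
                st.sampled_from("ACDEFG").map(lambda aa: PositionSpec("fixed", (aa,))),
                st.just(PositionSpec("class", ("D", "E"))),
                st.just(PositionSpec("wildcard")),
            ),
            min_size=1, max_size=6,
        ))
        motif = ConsensusMotif(positions=positions)
        assert match_motif(seq, motif) == regex_motif_oracle(seq, motif)


class TestClassifySequences:
    def test_planted_family_separates_cleanly(self):
        records, labels, truth = simulate_family(seed=31)
        motif = parse_motif(truth.truth["motif"])
        table = classify_sequences(dict(records), motif)
        for rid, seq in records:
            if labels[rid] == "high":
                assert table[rid], rid
        anchored = classify_sequences(
            dict(records), motif, region_window=tuple(truth.truth["region_span"])
        )
        for rid, seq in records:
            assert anchored[rid] == (labels[rid] == "high"), rid

    def test_planted_prevalence_recovered(self):
        rng_matches = 0
        records, labels, truth = simulate_family(seed=41, n_high=7, n_low=3)
        motif = parse_motif(truth.truth["motif"])
        table = classify_sequences(
            dict(records), motif, region_window=tuple(truth.truth["region_span"])
        )
        frac = sum(table.values()) / len(table)
        assert frac == pytest.approx(0.7)

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            classify_sequences({"a": "ACD"}, ConsensusMotif(positions=[]))


def test_profile_columns_frequencies_sum_to_one(ref_alignment):
    profiles = profile_columns(ref_alignment.records, [59, 60, 61])
    for p in profiles:
        for group, freqs in p.frequencies.items():
            if freqs:
                assert sum(freqs.values()) == pytest.approx(1.0)
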
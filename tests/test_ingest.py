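"""Format readers, alignment filtering, pileup and consensus calling."""

import numpy as np
import pytest

from strainmosaic import (
    AlignmentRecord,
    DepthTrack,
    ReferenceSequence,
    SNVProfile,
    call_consensus_snvs,
    filter_alignments,
    make_reference,
    mutate_strain,
    pileup,
    read_depth_tsv,
    read_fasta,
    read_sam,
    read_vcf,
    simulate_alignments,
    write_depth_tsv,
    write_vcf,
)
from strainmosaic.core import Pileup
from strainmosaic.synthetic_data import write_fasta, write_sam


def _record(**kw):
    base = dict(
        read_id="r1",
        species_id="sp",
        pos=1,
        aligned_length=100,
        edit_distance=0,
    )
    base.update(kw)
    return AlignmentRecord(**base)


class TestReadFasta:
    def test_two_records_round_trip(self, tmp_path):
        refs = [
            make_reference("spA", 1200, 0.4, seed=1),
            make_reference("spB", 2400, 0.6, seed=2),
        ]
        path = tmp_path / "refs.fa"
        write_fasta(refs, path)
        back = read_fasta(path)
        assert [(r.species_id, r.length) for r in back] == [("spA", 1200), ("spB", 2400)]
        assert back[0].sequence == refs[0].sequence

    def test_lowercase_uppercased_and_ambiguity_masked(self, tmp_path):
        path = tmp_path / "refs.fa"
        path.write_text(">s1\nacgtn\nRYacg\n")
        (ref,) = read_fasta(path)
        assert ref.sequence == "ACGTNNNACG"

    def test_masked_positions_never_callable(self):
        ref = ReferenceSequence("s", "s", "ANGT" * 300)
        counts = np.zeros((ref.length, 4), dtype=int)
        counts[:, 0] = 20  # all A, depth 20 everywhere
        prof = call_consensus_snvs(Pileup("s", counts), ref, "x")
        n_positions = [p for p in prof.calls if ref.sequence[p - 1] == "N"]
        assert n_positions == []

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "refs.fa"
        path.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "refs.fa"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(path)


class TestFilterAlignments:
    def test_identity_boundary_at_90_percent(self):
        ok = _record(edit_distance=10)  # identity 0.90
        bad = _record(edit_distance=11)  # identity 0.89
        kept, tally = filter_alignments([ok, bad])
        assert kept == [ok]
        assert tally.rejected == {"low-identity": 1}

    def test_secondary_rejected_despite_perfect_identity(self):
        rec = _record(is_secondary=True)
        kept, tally = filter_alignments([rec])
        assert kept == [] and tally.rejected == {"multi-mapped": 1}

    def test_degenerate_zero_length_rejected(self):
        kept, tally = filter_alignments([_record(aligned_length=0)])
        assert kept == [] and tally.rejected == {"degenerate": 1}

    def test_partition_and_idempotence(self, rng):
        records = [
            _record(
                read_id=f"r{i}",
                edit_distance=int(rng.integers(0, 20)),
                is_secondary=bool(rng.random() < 0.2),
            )
            for i in range(200)
        ]
        kept, tally = filter_alignments(records)
        assert len(kept) + sum(tally.rejected.values()) == len(records)
        kept2, tally2 = filter_alignments(kept)
        assert kept2 == kept and tally2.rejected == {}


class TestPileup:
    def test_no_records_gives_zero_track(self, small_reference):
        pu, track = pileup([], small_reference)
        assert track.depth.sum() == 0 and pu.counts.sum() == 0

    def test_single_read_depth_footprint(self, small_reference):
        rec = _record(
            species_id=small_reference.species_id,
            pos=1,
            sequence=small_reference.sequence[:100],
        )
        _, track = pileup([rec], small_reference)
        assert (track.depth[:100] == 1).all() and track.depth[100:].sum() == 0

    def test_read_conservation(self, small_reference, small_strain):
        recs = simulate_alignments(small_strain, 100, 80, seed=3)
        _, track = pileup(recs, small_reference)
        assert track.depth.sum() == sum(r.aligned_length for r in recs)

    def test_read_past_reference_end_rejected(self, small_reference):
        rec = _record(
            species_id=small_reference.species_id,
            pos=small_reference.length - 10,
            sequence="A" * 100,
        )
        with pytest.raises(ValueError, match="past reference end"):
            pileup([rec], small_reference)


class TestConsensusCaller:
    def test_fraction_and_depth_thresholds(self, small_reference):
        ref_base = small_reference.sequence[9]
        alt = "A" if ref_base != "A" else "C"
        alt_idx = "ACGT".index(alt)
        counts = np.zeros((small_reference.length, 4), dtype=int)
        counts[9, alt_idx] = 9
        counts[9, "ACGT".index(ref_base)] = 1  # depth 10, 90% alt -> called
        counts[19, alt_idx] = 4  # depth 4 < 5 -> not called
        prof = call_consensus_snvs(Pileup(small_reference.species_id, counts), small_reference, "s")
        assert prof.calls.get(10) == alt
        assert 20 not in prof.calls

    def test_exact_fraction_boundary_calls(self, small_reference):
        ref_base = small_reference.sequence[0]
        alt = "G" if ref_base != "G" else "T"
        counts = np.zeros((small_reference.length, 4), dtype=int)
        counts[0, "ACGT".index(alt)] = 4
        counts[0, "ACGT".index(ref_base)] = 1  # 4/5 = 0.8 exactly
        prof = call_consensus_snvs(Pileup(small_reference.species_id, counts), small_reference, "s")
        assert prof.calls.get(1) == alt


class TestSamRoundTrip:
    def test_write_then_read_preserves_records(self, tmp_path, small_reference, small_strain):
        recs = simulate_alignments(small_strain, 100, 30, error_rate=0.01, seed=5,
                                   secondary_fraction=0.1)
        path = tmp_path / "aln.sam"
        write_sam(recs, [small_reference], path)
        back = read_sam(path)
        assert len(back) == len(recs)
        by_id = {r.read_id: r for r in back}
        for r in recs:
            b = by_id[r.read_id]
            assert (b.pos, b.aligned_length, b.edit_distance, b.is_secondary) == (
                r.pos,
                r.aligned_length,
                r.edit_distance,
                r.is_secondary,
            )
            assert b.sequence == r.sequence


class TestVcfRoundTrip:
    def test_biallelic_round_trip_lossless(self, tmp_path, small_reference):
        ref = small_reference

        def alt_at(p):
            return "A" if ref.sequence[p - 1] != "A" else "C"

        prof_a = SNVProfile("sA", ref.species_id, {10: alt_at(10), 500: alt_at(500)},
                            {10: 12, 500: 8})
        prof_b = SNVProfile("sB", ref.species_id, {10: alt_at(10)}, {10: 15})
        path = tmp_path / "calls.vcf"
        write_vcf([prof_a, prof_b], {ref.species_id: ref}, path)
        back = read_vcf(path)
        assert back["sA"][ref.species_id].calls == prof_a.calls
        assert back["sB"][ref.species_id].calls == prof_b.calls
        assert back["sA"][ref.species_id].depth_at_call == prof_a.depth_at_call

    def test_missing_genotype_is_uncalled(self, tmp_path, small_reference):
        ref = small_reference
        alt = "A" if ref.sequence[4] != "A" else "C"
        prof = SNVProfile("sA", ref.species_id, {5: alt}, {5: 9})
        path = tmp_path / "calls.vcf"
        write_vcf([prof, SNVProfile("sB", ref.species_id)], {ref.species_id: ref}, path)
        back = read_vcf(path)
        assert back["sB"].get(ref.species_id) is None or not back["sB"][ref.species_id].calls

    def test_unknown_contig_rejected(self, tmp_path, small_reference):
        ref = small_reference
        alt = "A" if ref.sequence[4] != "A" else "C"
        prof = SNVProfile("sA", ref.species_id, {5: alt}, {5: 9})
        path = tmp_path / "calls.vcf"
        write_vcf([prof], {ref.species_id: ref}, path)
        with pytest.raises(ValueError, match="unknown contig"):
            read_vcf(path, known_contigs={"other"})


class TestDepthTsv:
    def test_empty_file_gives_all_zero_track(self, tmp_path):
        path = tmp_path / "depth.tsv"
        path.write_text("")
        track = read_depth_tsv(path, 1000, "sp")
        assert track.length == 1000 and track.depth.sum() == 0

    def test_sparse_rows_fill_zeros_and_round_trip(self, tmp_path):
        depth = np.zeros(500, dtype=int)
        depth[[3, 100, 499]] = [7, 2, 1]
        track = DepthTrack("sp", depth)
        path = tmp_path / "depth.tsv"
        write_depth_tsv([track], path)
        back = read_depth_tsv(path, 500, "sp")
        assert (back.depth == depth).all()

    def test_negative_depth_rejected(self, tmp_path):
        path = tmp_path / "depth.tsv"
        path.write_text("species\tpos\tdepth\nsp\t1\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            read_depth_tsv(path, 100, "sp")
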
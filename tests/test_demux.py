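"""Per-read engine: barcode assignment, masking, chimera splitting, trimming."""

import random

import numpy as np
import pytest

from demuxlr import (
    AssignmentStatus,
    BarcodeIndex,
    DemuxParams,
    Read,
    SimConfig,
    assign_barcode,
    default_structure,
    demultiplex_read,
    generate_whitelist,
    mask_interval,
    reverse_complement,
    simulate_reads,
)
from demuxlr import DEFAULT_POLYT, DEFAULT_PRIMER

from conftest import oracle_infix, random_seq


def make_read(bc, u, insert="ACGT" * 10, left="AATC", right="GGAT", rid="r0"):
    seq = left + DEFAULT_PRIMER + bc + u + DEFAULT_POLYT + insert + right
    return Read(id=rid, sequence=seq, qualities="I" * len(seq))


class TestAssignBarcode:
    def test_exact_barcode_assigned_at_zero(self):
        bc = "ACGTACGTACGTACGT"
        asn = assign_barcode("CCCC" + bc + "TTTT", [bc], barcode_max_d=2)
        assert asn.status is AssignmentStatus.ASSIGNED
        assert asn.barcode == bc and asn.distance == 0

    def test_equal_lowest_distance_is_ambiguous(self):
        window = "GGAAAACCCCGG"
        asn = assign_barcode(window, ["AAAACCCA", "AAAACCCT"], barcode_max_d=2)
        assert asn.status is AssignmentStatus.AMBIGUOUS

    def test_distance_beyond_bound_is_no_barcode(self):
        asn = assign_barcode("TTTTTTTTTT", ["ACGCAGGTCA"], barcode_max_d=2)
        assert asn.status is AssignmentStatus.NO_BARCODE

    def test_empty_whitelist_is_hard_error(self):
        with pytest.raises(ValueError, match="discovery"):
            assign_barcode("ACGT", [], barcode_max_d=2)

    def test_result_independent_of_whitelist_order(self):
        rng = random.Random(0)
        wl = generate_whitelist(20, 12, 3, seed=4)
        window = "AA" + wl[7] + "CC"
        shuffled = wl[:]
        rng.shuffle(shuffled)
        a = assign_barcode(window, wl, 2)
        b = assign_barcode(window, shuffled, 2)
        assert (a.barcode, a.distance, a.status) == (b.barcode, b.distance, b.status)

    def test_corrected_assignment_verified_by_bruteforce(self):
        # inject 2 edits into a barcode from a d>=5 whitelist, then confirm
        # the winner and its distance against the brute-force infix oracle
        from demuxlr.sim import _exact_edits

        rng = np.random.default_rng(1)
        wl = generate_whitelist(12, 16, 5, seed=5)
        for i in range(12):
            mutated = _exact_edits(wl[i], rng, 2)
            window = "CGAT" + mutated + "TTAGC"
            asn = assign_barcode(window, wl, barcode_max_d=2)
            dists = {b: oracle_infix(b, window, 16)[0] for b in wl}
            dmin = min(dists.values())
            winners = [b for b, dv in dists.items() if dv == dmin]
            if len(winners) == 1 and dmin <= 2:
                assert asn.status is AssignmentStatus.ASSIGNED
                assert asn.barcode == winners[0] == wl[i]
                assert asn.distance == dmin


class TestMaskInterval:
    def test_masks_with_sentinel(self):
        assert mask_interval("ACGTACGT", (2, 4)) == "ACXXACGT"

    def test_idempotent_on_overlap(self):
        once = mask_interval("ACGTACGT", (2, 6))
        assert mask_interval(once, (2, 6)) == once

    def test_out_of_bounds_is_error(self):
        with pytest.raises(ValueError):
            mask_interval("ACGT", (2, 9))


class TestDemultiplexRead:
    def test_error_free_singleton(self, structure):
        bc = "ACGGATTACCAGGTCA"
        u = "TTACGGACGTAC"
        read = make_read(bc, u)
        recs = demultiplex_read(read, structure, [bc, "A" * 16])
        assert len(recs) == 1
        a = recs[0].assignment
        assert a.status is AssignmentStatus.ASSIGNED
        assert (a.barcode, a.umi, a.distance) == (bc, u, 0)
        assert recs[0].strand == "+"
        assert recs[0].sub_read_index == 0

    def test_constructed_chimera_splits_into_both(self, structure):
        wl = generate_whitelist(4, 16, 5, seed=6)
        rng = random.Random(8)
        ins1, ins2 = random_seq(rng, 40), random_seq(rng, 35)
        r1 = make_read(wl[0], "A" * 12, insert=ins1, left="", right="")
        r2 = make_read(wl[1], "C" * 12, insert=ins2, left="", right="")
        chim = Read(id="chim", sequence=r1.sequence + r2.sequence)
        recs = demultiplex_read(chim, structure, wl)
        assert [r.assignment.barcode for r in recs] == [wl[0], wl[1]]
        assert [r.sub_read_index for r in recs] == [0, 1]
        assert [r.trimmed_sequence for r in recs] == [ins1, ins2]

    def test_reverse_complement_read_gives_same_call_flipped(self, structure):
        wl = generate_whitelist(4, 16, 5, seed=7)
        read = make_read(wl[2], "GTCAGTCAGTCA")
        fwd = demultiplex_read(read, structure, wl)
        rc = Read(id=read.id, sequence=reverse_complement(read.sequence))
        rev = demultiplex_read(rc, structure, wl)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].assignment.barcode == rev[0].assignment.barcode
        assert fwd[0].assignment.umi == rev[0].assignment.umi
        assert (fwd[0].strand, rev[0].strand) == ("+", "-")
        assert fwd[0].trimmed_sequence == rev[0].trimmed_sequence

    def test_no_flank_failure_record_passes_read_through(self, structure):
        read = Read(id="junk", sequence="ACGT" * 30)
        recs = demultiplex_read(read, structure, ["A" * 16])
        assert len(recs) == 1
        assert recs[0].status is AssignmentStatus.NO_FLANK
        assert recs[0].trimmed_sequence == read.sequence

    def test_split_disabled_caps_at_one_record(self, structure):
        wl = generate_whitelist(4, 16, 5, seed=6)
        r1 = make_read(wl[0], "A" * 12, left="", right="")
        r2 = make_read(wl[1], "C" * 12, left="", right="")
        chim = Read(id="chim", sequence=r1.sequence + r2.sequence)
        recs = demultiplex_read(
            chim, structure, wl, DemuxParams(split_chimeras=False)
        )
        assert len(recs) == 1
        assert recs[0].assignment.barcode == wl[0]

    def test_records_never_exceed_embedded_structures(self, structure):
        # property: at most 1 + number of embedded structure copies
        cfg = SimConfig(n_reads=30, chimera_rate=0.5, n_barcodes=8,
                        min_pairwise_distance=5, seed=9)
        reads, truth, wl = simulate_reads(cfg)
        index = BarcodeIndex(wl)
        for read in reads:
            embedded = (truth.read_id == read.id).sum()
            recs = demultiplex_read(read, structure, index)
            n_assigned = sum(
                1 for r in recs if r.status is AssignmentStatus.ASSIGNED
            )
            assert n_assigned <= 1 + embedded

    def test_umi_truncated_at_read_end_is_flagged(self, structure):
        bc = "ACGGATTACCAGGTCA"
        seq = "AAGG" + DEFAULT_PRIMER + bc + "GTCAG"  # only 5 UMI bases, no polyT
        read = Read(id="t", sequence=seq)
        recs = demultiplex_read(read, structure, [bc])
        a = recs[0].assignment
        if a.status is AssignmentStatus.ASSIGNED:
            assert a.umi_truncated
            assert len(a.umi) < 12

    def test_umi_before_barcode_layout(self):
        from demuxlr import ReadStructure, barcode, flank, umi

        s = ReadStructure(
            segments=(flank(DEFAULT_PRIMER), umi(6), barcode(10), flank("TTTTTT"))
        )
        bc, u = "ACGTACCACG", "GGCTAC"
        seq = "AT" + DEFAULT_PRIMER + u + bc + "TTTTTT" + "CGCG"
        recs = demultiplex_read(Read(id="x", sequence=seq), s, [bc])
        a = recs[0].assignment
        assert a.status is AssignmentStatus.ASSIGNED
        assert a.barcode == bc and a.umi == u

    def test_deterministic_across_repeats(self, structure):
        cfg = SimConfig(n_reads=20, n_barcodes=8, min_pairwise_distance=5, seed=10)
        reads, _, wl = simulate_reads(cfg)
        index = BarcodeIndex(wl)

        def run():
            return [
                (r.source_read_id, r.sub_read_index, r.assignment.barcode,
                 r.assignment.umi, r.strand, r.trimmed_sequence)
                for read in reads
                for r in demultiplex_read(read, structure, index)
            ]

        assert run() == run()


class TestGuaranteedCorrection:
    @pytest.mark.parametrize("k", [1, 2])
    def test_k_edits_in_barcode_always_corrected(self, structure, k):
        # whitelist min pairwise distance 2k+1 guarantees a unique nearest
        # neighbour when exactly k edits hit the barcode region
        cfg = SimConfig(
            n_reads=120, n_barcodes=24, min_pairwise_distance=2 * k + 1,
            barcode_exact_edits=k, chimera_rate=0.0, rc_fraction=0.0,
            junk_length_range=(0, 10), seed=11 + k,
        )
        reads, truth, wl = simulate_reads(cfg)
        index = BarcodeIndex(wl)
        tmap = truth.set_index("read_id")["barcode"]
        for read in reads:
            recs = demultiplex_read(read, structure, index)
            assert len(recs) == 1
            a = recs[0].assignment
            assert a.status is AssignmentStatus.ASSIGNED
            assert a.barcode == tmap[read.id]
            assert a.distance <= k
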
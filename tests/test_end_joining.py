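import numpy as np
import pytest

from helpers import best_single_deletion_placements

from dsbrepair.end_joining import (
    Alignment,
    Reject,
    align_to_reference,
    audit_unclassified,
    classify_read_1dsb,
    classify_library_1dsb,
    realign_encapsulate,
)
from dsbrepair.microhomology import build_signature, enumerate_pairs
from dsbrepair.read_prep import prepare_library
from dsbrepair.synthetic_data import EventMix, default_scheme, simulate_reads


class TestAlign:
    def test_reference_prefix_all_match(self):
        ref = "ACGTACGTACGTACGTACGT"
        aln = align_to_reference(ref[:12], ref)
        assert isinstance(aln, Alignment)
        assert aln.ops == [("M", 0, 12)]
        assert aln.n_mismatch == 0

    def test_read_missing_first_base_rejected(self, ctx_1dsb):
        ref = ctx_1dsb.reference
        res = align_to_reference(ref[1:140], ref)
        assert isinstance(res, Reject)

    def test_unrelated_read_rejected_by_score_floor(self, ctx_1dsb):
        rng = np.random.default_rng(0)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        res = align_to_reference(read, ctx_1dsb.reference)
        assert isinstance(res, Reject)

    def test_ops_tile_read_and_coords_increase(self, ctx_1dsb):
        ref = ctx_1dsb.reference
        read = ref[:50] + "TT" + ref[50:120]
        aln = align_to_reference(read, ref)
        read_len = sum(
            (p if isinstance(p, int) else len(p)) for k, _r, p in aln.ops if k in "MXI")
        assert read_len == len(read)
        ref_positions = [r for k, r, _p in aln.ops]
        assert ref_positions == sorted(ref_positions)


class TestRealign:
    def test_homopolymer_deletion_moved_to_cut(self):
        # deletion in a T homopolymer: the left-aligned placement is far from
        # the cut but an equivalent placement adjacent to the cut exists
        ref = "AAAATTTTCCCCGGGG"
        read = "AAAATTTCCCCGGGG"
        cut = 6
        aln = align_to_reference(read, ref)
        realigned = realign_encapsulate(aln, ref, cut)
        assert realigned.encapsulating
        assert realigned.n_mismatch == 0
        # exhaustive oracle: some placement touching the cut has 0 mismatches
        placements = best_single_deletion_placements(read, ref, 1)
        touching = {a: mm for a, mm in placements.items() if a <= cut <= a + 1}
        assert min(touching.values()) == 0

    def test_no_indels_returned_unchanged(self):
        ref = "ACGTACGTACGTACGT"
        aln = align_to_reference(ref[:10], ref)
        out = realign_encapsulate(aln, ref, 5)
        assert out.ops == [("M", 0, 10)]
        assert out.encapsulating

    def test_far_indel_kept_when_relocation_costs_mismatches(self, ctx_1dsb):
        ref = ctx_1dsb.reference
        cut = ctx_1dsb.cut
        # deletion 25 nt downstream of the cut
        read = ref[:cut + 25] + ref[cut + 28:cut + 90]
        aln = align_to_reference(read, ref)
        realigned = realign_encapsulate(aln, ref, cut)
        oracle = best_single_deletion_placements(read, ref, 3)
        touching = {a: mm for a, mm in oracle.items() if a <= cut <= a + 3}
        if min(touching.values()) > 0:  # relocation genuinely costs mismatches
            assert not realigned.encapsulating
            assert realigned.n_mismatch == aln.n_mismatch

    def test_never_increases_mismatches(self, ctx_1dsb):
        rng = np.random.default_rng(3)
        ref = ctx_1dsb.reference
        for _ in range(50):
            a = int(rng.integers(5, 100))
            d = int(rng.integers(1, 6))
            read = ref[:a] + ref[a + d:a + d + 60]
            aln = align_to_reference(read, ref)
            if not isinstance(aln, Alignment):
                continue
            before = aln.n_mismatch
            after = realign_encapsulate(aln, ref, ctx_1dsb.cut).n_mismatch
            assert after <= before


class TestClassify1DSB:
    def test_reference_read_error_free(self, ctx_1dsb):
        read = ctx_1dsb.reference[:144]
        call = classify_read_1dsb("r", read, ctx_1dsb.reference, ctx_1dsb.cut, 130, ctx_1dsb.signatures)
        assert call.category == "error_free_uncut"

    def test_short_read_rejected(self, ctx_1dsb):
        read = ctx_1dsb.reference[:100]
        call = classify_read_1dsb("r", read, ctx_1dsb.reference, ctx_1dsb.cut, 130, ctx_1dsb.signatures)
        assert call.category == "rejected_short"

    def test_indel_at_cut_is_nhej(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        read = ref[:cut] + "AT" + ref[cut:142]
        call = classify_read_1dsb("r", read, ref, cut, 130, ctx_1dsb.signatures)
        assert call.category == "nhej_indel"

    def test_zero_error_classification_matches_truth_exactly(self, sense_spec, ctx_1dsb):
        mix = EventMix({"error_free": 0.5, "nhej_ins:2": 0.2, "nhej_del:3": 0.3},
                       sub_error_rate=0.0, seed=11)
        records, truths = simulate_reads(sense_spec, mix, 2000, cut_a="sgA")
        accepted, _ = prepare_library(records, default_scheme(sense_spec))
        calls, _ = classify_library_1dsb(
            accepted, ctx_1dsb.reference, ctx_1dsb.cut, ctx_1dsb.signatures)
        truth = {t.read_id: t.true_event for t in truths}
        for c in calls:
            expected = "error_free_uncut" if truth[c.read_id] == "error_free" else "nhej_indel"
            assert c.category == expected

    def test_category_frequencies_partition(self, sense_spec, ctx_1dsb):
        mix = EventMix({"error_free": 0.6, "nhej_del:4": 0.3, "noise": 0.1},
                       sub_error_rate=0.002, seed=13)
        records, _ = simulate_reads(sense_spec, mix, 1000, cut_a="sgA")
        accepted, _ = prepare_library(records, default_scheme(sense_spec))
        _, freqs = classify_library_1dsb(
            accepted, ctx_1dsb.reference, ctx_1dsb.cut, ctx_1dsb.signatures)
        partition = [
            "error_free_uncut", "nhej_indel", "mmej", "rejected_short",
            "rejected_unaligned", "rejected_not_encapsulating",
        ]
        assert sum(freqs[c] for c in partition) == pytest.approx(1.0)


class TestAudit:
    def test_shifted_deletion_within_3nt(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        # find a small deletion 1-3 nt from the cut that cannot be
        # re-represented at the cut without mismatches
        case = None
        for shift in (1, 2, 3):
            for d in (1, 2, 3):
                read = ref[:cut + shift] + ref[cut + shift + d:cut + 90]
                oracle = best_single_deletion_placements(read, ref, d)
                touching = {a: mm for a, mm in oracle.items() if a <= cut <= a + d}
                if min(touching.values()) > 0:
                    case = read
                    break
            if case:
                break
        assert case is not None
        cat = audit_unclassified(case, ref, cut, ctx_1dsb.construct.amplicon_regions(),
                                 ctx_1dsb.construct.amplicon_excluded())
        assert cat == "shifted_le3"

    def test_exon_branch_deletion(self, sense_spec):
        regions = sense_spec.amplicon_regions()
        excluded = sense_spec.amplicon_excluded()
        ref = sense_spec.amplicon
        cut = sense_spec.to_amplicon_coord(sense_spec.cut_sites["sgA"])
        bs, be = excluded["branch_site"]
        read = ref[:cut - 5] + ref[bs + 10:bs + 10 + 90]
        cat = audit_unclassified(read, ref, cut, regions, excluded)
        assert cat == "exon_branch_del"

    def test_scattered_indels_are_other(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        read = ref[:20] + "AA" + ref[20:80] + "TT" + ref[80:130]
        cat = audit_unclassified(read, ref, cut, ctx_1dsb.construct.amplicon_regions(),
                                 ctx_1dsb.construct.amplicon_excluded())
        assert cat == "other"


class TestOverlapAccounting:
    def test_cut_proximal_microhomology_counts_once_with_overlap(self):
        # a cut-proximal pair makes a read that is simultaneously a valid
        # NHEJ-style deletion at the cut and an exact MMEJ product; the read
        # is assigned to MMEJ and the overlap is recorded separately
        from dsbrepair.pipeline import make_context
        from dsbrepair.synthetic_data import make_construct

        spec = make_construct(6)  # carries a diagnostic pair with a <=10-nt deletion
        ctx = make_context(spec, "sgA")
        names = {s.pair.name for s in ctx.signatures}
        pair = next(p for p in ctx.pairs if p.deletion_size <= 10 and p.name in names)
        ref, cut = ctx.reference, ctx.cut
        s, e = pair.deletion_interval
        read = (ref[:s] + ref[e:])[:144]
        call = classify_read_1dsb("r", read, ref, cut, 130, ctx.signatures)
        assert call.category == "mmej"
        assert call.overlap_nhej
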
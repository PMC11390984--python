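import math

import pytest

from dsbrepair.gap_repair import (
    classify_by_length,
    classify_library_2dsb,
    classify_short_read,
    classify_three_refs,
    detect_flipped,
    make_flip_probe,
    rtdr_scan,
    yeast_intron_status,
)
from dsbrepair.read_prep import prepare_library
from dsbrepair.reference_model import ConstructError, derive_references
from dsbrepair.synthetic_data import (
    EventMix,
    default_scheme,
    pick_mmej_pair,
    simulate_reads,
)


class TestLengthRule:
    @pytest.mark.parametrize("length,expected", [
        (150, "with_intron"),
        (118, "short"),
        (130, "short"),   # boundary: strictly longer than 130 counts as intron
        (131, "with_intron"),
    ])
    def test_threshold_is_strict(self, length, expected):
        assert classify_by_length("A" * length) == expected


class TestShortReads:
    def test_gap_deleted_reference_is_nhej(self, ctx_2dsb):
        cat, pairs = classify_short_read(ctx_2dsb.refs.ref_2dsb, ctx_2dsb.signatures)
        assert cat == "popout_nhej" and not pairs

    def test_junction_insertion_is_nhej(self, ctx_2dsb):
        ref2, cut = ctx_2dsb.refs.ref_2dsb, ctx_2dsb.refs.cut_in_ref2
        read = ref2[:cut] + "TT" + ref2[cut:]
        assert classify_short_read(read, ctx_2dsb.signatures)[0] == "popout_nhej"

    def test_planted_mmej_product_detected(self, sense_spec, ctx_2dsb):
        pair = pick_mmej_pair(sense_spec, sense_spec.cut_sites["sgU"], sense_spec.cut_sites["sgD"])
        s, e = pair.deletion_interval
        product = sense_spec.amplicon[:s] + sense_spec.amplicon[e:]
        cat, names = classify_short_read(product, ctx_2dsb.signatures)
        assert cat == "popout_mmej" and pair.name in names


class TestFlipDetection:
    def test_probe_absent_from_unbroken_references(self, sense_spec, ctx_2dsb):
        probe = make_flip_probe(sense_spec, "sgU", "sgD")
        assert probe not in ctx_2dsb.refs.ref_1dsb
        assert probe not in ctx_2dsb.refs.ref_2dsb

    def test_flipped_read_detected(self, sense_spec, ctx_2dsb):
        probe = make_flip_probe(sense_spec, "sgU", "sgD")
        assert detect_flipped(ctx_2dsb.refs.ref_flipped[:144], probe)

    def test_intact_and_gap_reads_not_detected(self, sense_spec, ctx_2dsb):
        probe = make_flip_probe(sense_spec, "sgU", "sgD")
        assert not detect_flipped(ctx_2dsb.refs.ref_1dsb[:144], probe)
        assert not detect_flipped(ctx_2dsb.refs.ref_2dsb, probe)

    def test_non_diagnostic_probe_is_config_error(self, sense_spec):
        # offset beyond the flipped segment re-enters unbroken sequence
        with pytest.raises(ConstructError):
            make_flip_probe(sense_spec, "sgU", "sgD", offset=150)


class TestThreeReferenceMode:
    def refs(self, ctx):
        return {"no_dsb": ctx.refs.ref_1dsb, "gap_repair": ctx.refs.ref_2dsb,
                "flipped": ctx.refs.ref_flipped}

    def test_intact_read_is_segment_retention(self, ctx_2dsb):
        cat, flip = classify_three_refs(ctx_2dsb.refs.ref_1dsb[:144], self.refs(ctx_2dsb), ctx_2dsb.signatures)
        assert cat == "segment_retention" and not flip

    def test_flipped_read_retention_plus_flip_count(self, ctx_2dsb):
        cat, flip = classify_three_refs(ctx_2dsb.refs.ref_flipped[:144], self.refs(ctx_2dsb), ctx_2dsb.signatures)
        assert cat == "segment_retention" and flip

    def test_gap_read_is_popout(self, ctx_2dsb):
        cat, _ = classify_three_refs(ctx_2dsb.refs.ref_2dsb, self.refs(ctx_2dsb), ctx_2dsb.signatures)
        assert cat == "popout_nhej"

    def test_garbage_unclassified(self, ctx_2dsb):
        cat, _ = classify_three_refs("ACGT" * 30, self.refs(ctx_2dsb), ctx_2dsb.signatures)
        assert cat == "unclassified"


class TestYeastMode:
    def test_lengths(self, yeast_spec):
        refs = derive_references(yeast_spec, "sgU", "sgD")
        assert len(refs.ref_1dsb) == 425
        assert len(refs.ref_2dsb) == 196

    def test_intron_status_by_exon3_kmers(self, yeast_spec):
        refs = derive_references(yeast_spec, "sgU", "sgD")
        e2s, e2e = yeast_spec.amplicon_regions()["Exon2"]
        exon3 = yeast_spec.amplicon[e2s:e2e]
        assert yeast_intron_status(refs.ref_1dsb[:144], exon3) == "intron_retained"
        assert yeast_intron_status(refs.ref_2dsb[:144], exon3) == "intron_lost"

    def test_short_exon3_is_error(self):
        with pytest.raises(ValueError):
            yeast_intron_status("A" * 100, "ACGTACGT")

    def test_rtdr_recovery_within_3_sigma(self, yeast_spec):
        n, frac = 10_000, 0.02
        mix = EventMix({"error_free": 0.6, "popout": 1 - 0.6 - frac, "rtdr": frac}, seed=21)
        records, _ = simulate_reads(yeast_spec, mix, n, cut_a="sgU", cut_b="sgD")
        accepted, _ = prepare_library(records, default_scheme(yeast_spec))
        i0, i1 = yeast_spec.amplicon_regions()["Intron"]
        spliced = yeast_spec.amplicon[:i0] + yeast_spec.amplicon[i1:]
        probe = spliced[i0 - 20:i0 + 20]
        freq = rtdr_scan([s for _, s in accepted], probe)
        tol = 3 * math.sqrt(frac * (1 - frac) / n)
        assert abs(freq - frac) <= tol

    def test_gap_junction_not_counted_as_rtdr(self, yeast_spec):
        refs = derive_references(yeast_spec, "sgU", "sgD")
        i0, i1 = yeast_spec.amplicon_regions()["Intron"]
        spliced = yeast_spec.amplicon[:i0] + yeast_spec.amplicon[i1:]
        probe = spliced[i0 - 20:i0 + 20]
        assert rtdr_scan([refs.ref_2dsb], probe) == 0.0


class TestLibraryClassification:
    def test_zero_error_recovery_exact(self, sense_spec, ctx_2dsb):
        pair = pick_mmej_pair(sense_spec, sense_spec.cut_sites["sgU"], sense_spec.cut_sites["sgD"])
        mix = EventMix({"error_free": 0.4, "popout": 0.3, f"mmej:{pair.name}": 0.2, "flipped": 0.1},
                       sub_error_rate=0.0, seed=31)
        records, truths = simulate_reads(sense_spec, mix, 2000, cut_a="sgU", cut_b="sgD")
        accepted, _ = prepare_library(records, default_scheme(sense_spec))
        calls, freqs = classify_library_2dsb(accepted, ctx_2dsb.signatures, ctx_2dsb.flip_probe)
        truth = {t.read_id: t.true_event for t in truths}
        expected = {"error_free": "with_intron_retained", "popout": "popout_nhej",
                    f"mmej:{pair.name}": "popout_mmej", "flipped": "with_intron_retained"}
        for c in calls:
            assert c.category == expected[truth[c.read_id]]
            assert c.flipped == (truth[c.read_id] == "flipped")
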
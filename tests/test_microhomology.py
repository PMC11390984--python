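import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_pairs

from dsbrepair.microhomology import (
    build_signature,
    detect_mmej,
    enumerate_pairs,
    mmej_frequencies,
)

TOY = "ACGCATTACGTCATGG"  # one maximal CAT/CAT pair around a cut at 8


def as_set(pairs):
    return {(p.up_interval, p.down_interval, p.segment) for p in pairs}


class TestEnumerate:
    def test_toy_reference_single_pair(self):
        pairs = enumerate_pairs(TOY, 8, min_len=3)
        assert as_set(pairs) == {((3, 6), (11, 14), "CAT")}
        assert as_set(pairs) == brute_force_pairs(TOY, 8, 8, min_len=3)

    def test_toy_min_len_4_empty(self):
        assert enumerate_pairs(TOY, 8, min_len=4) == []
        assert brute_force_pairs(TOY, 8, 8, min_len=4) == set()

    def test_excluded_interval_filters_pair(self):
        pairs = enumerate_pairs(TOY, 8, excluded_intervals={"x": (4, 5)}, min_len=3)
        assert pairs == []

    def test_deterministic_order(self):
        ref = TOY * 3
        a = enumerate_pairs(ref, 20, min_len=3)
        b = enumerate_pairs(ref, 20, min_len=3)
        assert [p.name for p in a] == [p.name for p in b]
        starts = [(p.up_interval[0], p.down_interval[0]) for p in a]
        assert starts == sorted(starts)

    def test_intervals_never_cross_the_cuts(self, sense_spec):
        cu = sense_spec.to_amplicon_coord(sense_spec.cut_sites["sgU"])
        cd = sense_spec.to_amplicon_coord(sense_spec.cut_sites["sgD"])
        pairs = enumerate_pairs(sense_spec.amplicon, cu, cd)
        for p in pairs:
            assert p.up_interval[1] <= cu
            assert p.down_interval[0] >= cd

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(40, 120), st.integers(3, 5))
    def test_matches_bruteforce_on_random_sequences(self, seed, length, min_len):
        rng = np.random.default_rng(seed)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        cut = int(rng.integers(5, length - 5))
        got = as_set(enumerate_pairs(ref, cut, min_len=min_len))
        assert got == brute_force_pairs(ref, cut, cut, min_len=min_len)


class TestSignature:
    def test_toy_signature(self):
        pair = enumerate_pairs(TOY, 8, min_len=3)[0]
        sig = build_signature(pair, TOY)
        assert sig.sequence == "ACGCATGG"
        # equals the reference with the MMEJ deletion applied
        s, e = pair.deletion_interval
        assert sig.sequence in TOY[:s] + TOY[e:]

    def test_signature_is_substring_of_deleted_reference(self, ctx_1dsb):
        ref = ctx_1dsb.refs.ref_1dsb
        for pair in ctx_1dsb.pairs:
            sig = build_signature(pair, ref)
            s, e = pair.deletion_interval
            assert sig.sequence in ref[:s] + ref[e:]

    def test_full_flanks_away_from_boundaries(self, ctx_1dsb):
        ref = ctx_1dsb.refs.ref_1dsb
        for pair in ctx_1dsb.pairs:
            if pair.up_interval[0] >= 10 and pair.down_interval[1] + 10 <= len(ref):
                sig = build_signature(pair, ref)
                assert len(sig.sequence) == 20 + len(pair.segment)


class TestDetect:
    def test_detects_planted_product(self):
        pair = enumerate_pairs(TOY, 8, min_len=3)[0]
        sig = build_signature(pair, TOY)
        s, e = pair.deletion_interval
        product = TOY[:s] + TOY[e:]
        assert detect_mmej(product, [sig]) == {pair.name}

    def test_intact_reference_not_detected(self):
        pair = enumerate_pairs(TOY, 8, min_len=3)[0]
        sig = build_signature(pair, TOY)
        assert detect_mmej(TOY, [sig]) == set()

    def test_single_substitution_defeats_exact_match(self):
        pair = enumerate_pairs(TOY, 8, min_len=3)[0]
        sig = build_signature(pair, TOY)
        s, e = pair.deletion_interval
        product = list(TOY[:s] + TOY[e:])
        product[4] = "A" if product[4] != "A" else "T"
        assert detect_mmej("".join(product), [sig]) == set()


class TestFrequencies:
    def test_arithmetic(self):
        detections = [set() for _ in range(990)] + [{"P"} for _ in range(10)]
        out = mmej_frequencies(detections, 1000)
        assert out["per_pair"]["P"] == pytest.approx(0.01)
        assert out["mmej_total"] == pytest.approx(0.01)

    def test_no_detections_all_zero(self):
        out = mmej_frequencies([set(), set()], 2)
        assert out["per_pair"] == {} and out["mmej_total"] == 0.0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            mmej_frequencies([], 0)

    def test_multi_pair_read_counts_once_in_total(self):
        out = mmej_frequencies([{"A", "B"}], 1)
        assert out["per_pair"] == {"A": 1.0, "B": 1.0}
        assert out["mmej_total"] == 1.0

    def test_category_split(self, ctx_1dsb):
        pairs = ctx_1dsb.pairs
        exon_intron = next(p for p in pairs if "Intron" in p.category)
        out = mmej_frequencies([{exon_intron.name}], 1, pairs=pairs)
        assert out["exon_intron_total"] == 1.0
        assert out["exon_exon_total"] == 0.0
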
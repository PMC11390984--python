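import pytest

from helpers import indel_distance

from dsbrepair.end_joining import align_to_reference, realign_encapsulate
from dsbrepair.variation_graphs import (
    DSBWindow,
    build_graph,
    extract_window,
    is_single_indel_neighbor,
    merge_window_tables,
    position_histogram,
    window_table,
)


def windowed(ctx, read):
    aln = align_to_reference(read, ctx.reference)
    aln = realign_encapsulate(aln, ctx.reference, ctx.cut)
    return extract_window(aln, ctx.reference, ctx.cut)


class TestExtraction:
    def test_perfect_read_gives_reference_window(self, ctx_1dsb):
        w = windowed(ctx_1dsb, ctx_1dsb.reference[:144])
        ref20 = ctx_1dsb.reference[ctx_1dsb.cut - 10:ctx_1dsb.cut + 10]
        assert w.sequence == ref20
        assert w.var_type == "none" and w.var_count == 0

    def test_single_insertion_at_cut(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        w = windowed(ctx_1dsb, ref[:cut] + "T" + ref[cut:143])
        assert len(w.sequence) == 21
        assert w.var_type == "insertion" and w.var_count == 1
        assert w.ins_point == 1  # junction bin

    def test_deletion_window_shorter(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        w = windowed(ctx_1dsb, ref[:cut] + ref[cut + 3:144])
        assert w.var_type == "deletion" and w.var_count == 3
        assert len(w.sequence) == 17

    def test_two_left_anchor_substitutions_rejected(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        read = list(ref[:144])
        for off in (15, 25):  # inside the -30..-11 anchor
            pos = cut - off
            read[pos] = "A" if ref[pos] != "A" else "T"
        assert windowed(ctx_1dsb, "".join(read)) == "anchor"

    def test_one_anchor_substitution_tolerated_and_masked(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        read = list(ref[:144])
        pos = cut - 15
        read[pos] = "A" if ref[pos] != "A" else "T"
        w = windowed(ctx_1dsb, "".join(read))
        assert w.sequence == ref[cut - 10:cut + 10]

    def test_window_substitutions_masked_to_reference(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        read = list(ref[:144])
        read[cut] = "A" if ref[cut] != "A" else "T"
        w = windowed(ctx_1dsb, "".join(read))
        assert w.sequence == ref[cut - 10:cut + 10]
        assert w.var_count == 0

    def test_read_not_spanning_anchor_rejected(self, ctx_1dsb):
        read = ctx_1dsb.reference[:ctx_1dsb.cut + 15]
        assert windowed(ctx_1dsb, read) == "span"


class TestTable:
    def test_per_repeat_frequency_and_mean(self):
        w = DSBWindow("ACGT", "none", 0)
        table = window_table([[w] * 5, []], totals=[1000, 1000])
        row = table.loc["ACGT"]
        assert row["freq_1"] == pytest.approx(0.005)
        assert row["freq_2"] == 0.0
        assert row["mean_freq"] == pytest.approx(0.0025)

    def test_mean_over_four_repeats_with_two_absences(self):
        w = DSBWindow("ACGT", "none", 0)
        table = window_table([[w] * 4, [w] * 4, [], []], totals=[1000] * 4)
        assert table.loc["ACGT", "mean_freq"] == pytest.approx(0.002)

    def test_merged_runs_recompute_over_concatenated_totals(self):
        w = DSBWindow("ACGT", "none", 0)
        merged = merge_window_tables([[w] * 2], [100], [[w] * 2], [300])
        assert merged.loc["ACGT", "freq_1"] == pytest.approx(4 / 400)

    def test_zero_repeats_error(self):
        with pytest.raises(ValueError):
            window_table([], [])


class TestGraph:
    def make_table(self, windows, counts, total=10_000):
        per_rep = []
        for w, c in zip(windows, counts):
            per_rep.extend([w] * c)
        return window_table([per_rep], [total])

    def test_reference_plus_insertion_two_vertices_one_edge(self):
        ref = "ACGTACGTACGTACGTACGT"
        wref = DSBWindow(ref, "none", 0)
        wins = DSBWindow(ref[:10] + "T" + ref[10:], "insertion", 1, ins_seq="T", ins_point=1)
        g = build_graph(self.make_table([wref, wins], [500, 100]))
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1

    def test_insertion_a_left_of_t(self):
        ref = "ACGTACGTACGTACGTACGT"
        wa = DSBWindow(ref[:10] + "A" + ref[10:], "insertion", 1, ins_seq="A", ins_point=1)
        wt = DSBWindow(ref[:10] + "T" + ref[10:], "insertion", 1, ins_seq="T", ins_point=1)
        g = build_graph(self.make_table([wa, wt], [100, 100]))
        assert g.nodes[wa.sequence]["x"] < g.nodes[wt.sequence]["x"]

    def test_min_freq_filter_drops_rare_windows(self):
        ref = "ACGTACGTACGTACGTACGT"
        wref = DSBWindow(ref, "none", 0)
        rare = DSBWindow(ref[1:], "deletion", 1, del_positions=(-10,))
        table = window_table([[wref] * 500, [wref] * 500 + [rare]], totals=[100_000, 100_000])
        g = build_graph(table, min_freq=1e-5)
        assert rare.sequence not in g
        assert wref.sequence in g

    def test_reference_vertex_unique_at_y0(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        reads = [ref[:144]] * 50
        reads += [ref[:cut] + "G" + ref[cut:143]] * 20
        reads += [ref[:cut] + ref[cut + 2:144]] * 20
        wins = [windowed(ctx_1dsb, r) for r in reads]
        g = build_graph(window_table([wins], [len(reads)]), min_freq=1e-5)
        zero = [n for n, d in g.nodes(data=True) if d["y"] == 0]
        assert zero == [ref[cut - 10:cut + 10]]

    def test_edges_match_indel_distance_oracle(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        reads = [ref[:144]] * 10
        for ins in ("A", "C", "G", "T", "AT", "GG"):
            reads += [ref[:cut] + ins + ref[cut:140]] * 3
        for d in (1, 2, 3):
            reads += [ref[:cut] + ref[cut + d:144]] * 3
            reads += [ref[:cut - d] + ref[cut:144]] * 3
        wins = [windowed(ctx_1dsb, r) for r in reads]
        assert all(not isinstance(w, str) for w in wins)
        g = build_graph(window_table([wins], [len(reads)]), min_freq=1e-9)
        nodes = list(g.nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                assert g.has_edge(a, b) == (indel_distance(a, b) == 1)

    def test_neighbor_check_agrees_with_dp(self):
        cases = [("ACGT", "ACGGT"), ("ACGT", "ACGT"), ("AAAA", "AAA"), ("ACGT", "AGCT"), ("ACGT", "TACGT")]
        for a, b in cases:
            assert is_single_indel_neighbor(a, b) == (indel_distance(a, b) == 1)


class TestHistogram:
    def test_single_insertion_mass_at_junction(self):
        ref = "ACGTACGTACGTACGTACGT"
        w = DSBWindow(ref[:10] + "T" + ref[10:], "insertion", 1, ins_seq="T", ins_point=1)
        hist = position_histogram(window_table([[w] * 10], [100]))
        assert hist.loc[1, "insertion_freq"] == pytest.approx(0.1)
        assert hist["insertion_freq"].sum() == pytest.approx(0.1)
        assert hist["deletion_freq"].sum() == 0.0

    def test_three_nt_deletion_spreads_over_three_bins(self):
        ref = "ACGTACGTACGTACGTACGT"
        w = DSBWindow(ref[:10] + ref[13:], "deletion", 3, del_positions=(1, 2, 3))
        hist = position_histogram(window_table([[w] * 10], [100]))
        for p in (1, 2, 3):
            assert hist.loc[p, "deletion_freq"] == pytest.approx(0.1)
        assert hist["deletion_freq"].sum() == pytest.approx(0.3)

    def test_mass_conservation(self, ctx_1dsb):
        ref, cut = ctx_1dsb.reference, ctx_1dsb.cut
        reads = [ref[:144]] * 20
        reads += [ref[:cut] + "AT" + ref[cut:140]] * 5
        reads += [ref[:cut] + ref[cut + 4:144]] * 5
        wins = [windowed(ctx_1dsb, r) for r in reads]
        table = window_table([wins], [len(reads)])
        hist = position_histogram(table)
        dele = table[table["var_type"] == "deletion"]
        ins = table[table["var_type"] == "insertion"]
        assert hist["deletion_freq"].sum() == pytest.approx(
            (dele["mean_freq"] * dele["var_count"]).sum())
        assert hist["insertion_freq"].sum() == pytest.approx(ins["mean_freq"].sum())
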
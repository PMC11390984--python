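"""DSB-sequence windows, variation-distance graphs and position histograms.

The *DSB-sequence window* of a read is the read sequence aligned to
reference positions -10..+10 around the cut (20 reference nucleotides, plus
any inserted bases, minus any deleted ones).  Reads qualify only when their
two 20-nt *anchors* (-30..-11 and +11..+30) align with at most one mismatch
and no in/del, which confines the captured variation to the window.
Substitutions inside the window are masked back to the reference base, so
windows differ from the reference 20-mer by in/dels only.

Windows are aggregated per repeat (frequency = reads with that window /
total reads in the library), averaged across repeats, and drawn as a graph:
one vertex per window, placed at y = +/- (number of varied nucleotides)
(insertions up, deletions down, reference at 0), x by alphabetical order of
the inserted sequence or by first-deleted position, sized by log mean
frequency, with an edge wherever two windows differ by exactly one
single-nucleotide in/del.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import networkx as nx
import pandas as pd

from .end_joining import Alignment


@dataclass(frozen=True)
class DSBWindow:
    sequence: str
    var_type: str            # none | insertion | deletion | mixed
    var_count: int
    ins_seq: str = ""        # concatenated inserted bases inside the window
    ins_point: int | None = None   # relative label of the insertion point
    del_positions: tuple[int, ...] = ()   # relative labels of deleted bases


def _rel_label(ref_pos: int, cut: int) -> int:
    """Signed position label relative to the cut (no position 0)."""
    return ref_pos - cut + 1 if ref_pos >= cut else ref_pos - cut


def extract_window(aln: Alignment, reference: str, cut: int,
                   half: int = 10, anchor: int = 20) -> DSBWindow | str:
    """Window around the cut, or a rejection reason string.

    Rejections: ``span`` (read does not cover both anchors), ``anchor``
    (>=2 mismatches or >=1 in/del within either anchor).
    """
    w_lo, w_hi = cut - half, cut + half
    a_lo, a_hi = w_lo - anchor, w_hi + anchor
    if a_lo < 0 or a_hi > len(reference):
        return "span"
    if aln.ref_end < a_hi:
        return "span"
    left_mm = right_mm = 0
    left_indel = right_indel = False
    win_chars: list[tuple[int, str]] = []      # (ref_pos, char) for aligned bases
    ins_runs: list[tuple[int, str]] = []       # (ref_pos, inserted seq) in window
    del_positions: list[int] = []
    for kind, pos, payload in aln.ops:
        if kind in ("M", "X"):
            end = pos + payload
            if kind == "X":
                left_mm += max(0, min(end, w_lo) - max(pos, a_lo))
                right_mm += max(0, min(end, a_hi) - max(pos, w_hi))
            s, e = max(pos, w_lo), min(end, w_hi)
            for p in range(s, e):
                win_chars.append((p, reference[p]))  # substitutions masked to reference
        elif kind == "D":
            end = pos + payload
            if max(pos, a_lo) < min(end, w_lo) or max(pos, w_hi) < min(end, a_hi):
                if max(pos, a_lo) < min(end, w_lo):
                    left_indel = True
                if max(pos, w_hi) < min(end, a_hi):
                    right_indel = True
            for p in range(max(pos, w_lo), min(end, w_hi)):
                del_positions.append(p)
        elif kind == "I":
            if a_lo < pos <= w_lo:
                left_indel = True
            elif w_hi <= pos < a_hi:
                right_indel = True
            elif w_lo < pos < w_hi:
                ins_runs.append((pos, payload))
    if left_indel or right_indel or left_mm >= 2 or right_mm >= 2:
        return "anchor"
    # assemble the window sequence in reference order with insertions in place
    parts: list[str] = []
    ins_by_pos = {}
    for pos, seq in ins_runs:
        ins_by_pos[pos] = ins_by_pos.get(pos, "") + seq
    covered = dict(win_chars)
    for p in range(w_lo, w_hi):
        if p in ins_by_pos:
            parts.append(ins_by_pos[p])
        if p in covered:
            parts.append(covered[p])
    ins_seq = "".join(seq for _, seq in ins_runs)
    n_ins, n_del = len(ins_seq), len(del_positions)
    if n_ins and n_del:
        var_type = "mixed"
    elif n_ins:
        var_type = "insertion"
    elif n_del:
        var_type = "deletion"
    else:
        var_type = "none"
    return DSBWindow(
        sequence="".join(parts),
        var_type=var_type,
        var_count=n_ins + n_del,
        ins_seq=ins_seq,
        ins_point=_rel_label(ins_runs[0][0], cut) if ins_runs else None,
        del_positions=tuple(sorted(_rel_label(p, cut) for p in del_positions)),
    )


def window_table(windows_per_repeat: list[list[DSBWindow]], totals: list[int]) -> pd.DataFrame:
    """Merge windows per repeat and average frequencies across repeats.

    ``totals`` are the per-repeat library sizes (the frequency denominator:
    all barcode-accepted reads).  Windows absent from a repeat contribute
    frequency 0 to the average.  Indexed by window sequence.
    """
    n_rep = len(windows_per_repeat)
    if n_rep == 0:
        raise ValueError("need at least one repeat")
    if len(totals) != n_rep or any(t <= 0 for t in totals):
        raise ValueError("totals must give a positive read count per repeat")
    meta: dict[str, DSBWindow] = {}
    counts: list[dict[str, int]] = []
    for wins in windows_per_repeat:
        c: dict[str, int] = {}
        for w in wins:
            c[w.sequence] = c.get(w.sequence, 0) + 1
            meta.setdefault(w.sequence, w)
        counts.append(c)
    rows = []
    for seq, w in meta.items():
        freqs = [counts[r].get(seq, 0) / totals[r] for r in range(n_rep)]
        rows.append(
            {
                "sequence": seq,
                "var_type": w.var_type,
                "var_count": w.var_count,
                "ins_seq": w.ins_seq,
                "ins_point": w.ins_point,
                "del_positions": w.del_positions,
                **{f"freq_{r + 1}": f for r, f in enumerate(freqs)},
                "mean_freq": sum(freqs) / n_rep,
            }
        )
    df = pd.DataFrame(rows).set_index("sequence").sort_index()
    df.attrs["n_repeats"] = n_rep
    return df


def merge_window_tables(counts_a: list[list[DSBWindow]], totals_a: list[int],
                        counts_b: list[list[DSBWindow]], totals_b: list[int]) -> pd.DataFrame:
    """Recompute one table from two sequencing runs of the same libraries
    (per-repeat windows concatenated, totals summed)."""
    merged = [wa + wb for wa, wb in zip(counts_a, counts_b)]
    totals = [ta + tb for ta, tb in zip(totals_a, totals_b)]
    return window_table(merged, totals)


# -- graph construction ----------------------------------------------------

def _lex_fraction(seq: str) -> float:
    """Map a DNA string to (0,1) by base-4 lexicographic value."""
    val = 0.0
    scale = 1.0
    for ch in seq:
        scale /= 4
        val += "ACGT".index(ch) * scale
    return val + scale / 2


def is_single_indel_neighbor(a: str, b: str) -> bool:
    """True iff one sequence is the other with exactly one nucleotide deleted."""
    if len(a) > len(b):
        a, b = b, a
    if len(b) - len(a) != 1:
        return False
    i = 0
    while i < len(a) and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def _passes_min_freq(row, n_rep: int, min_freq: float) -> bool:
    return all(row[f"freq_{r + 1}"] > min_freq for r in range(n_rep))


def build_graph(table: pd.DataFrame, min_freq: float = 1e-5,
                reference_window: str | None = None) -> nx.Graph:
    """Variation-distance graph from a window table.

    Windows whose frequency is <= ``min_freq`` in at least one repeat are
    dropped; mixed insertion+deletion windows are excluded from the layout
    (reported separately by the caller).  Vertex attributes: ``x``, ``y``,
    ``size`` (monotone in log10 mean frequency), ``var_type``, ``mean_freq``.
    """
    n_rep = table.attrs.get("n_repeats", sum(1 for c in table.columns if c.startswith("freq_")))
    kept = table[[_passes_min_freq(row, n_rep, min_freq) for _, row in table.iterrows()]]
    kept = kept[kept["var_type"] != "mixed"]
    g = nx.Graph()
    if kept.empty:
        return g
    fmin = kept["mean_freq"].min()
    for seq, row in kept.iterrows():
        y = float(row["var_count"])
        if row["var_type"] == "deletion":
            y = -y
        if row["var_type"] == "insertion":
            x = 2.0 * _lex_fraction(row["ins_seq"]) - 1.0
            if row["var_count"] >= 3:   # stagger dense insertion levels
                x_rank = int(_lex_fraction(row["ins_seq"]) * 4 ** min(row["var_count"], 8))
                y += 0.2 * ((x_rank % 3) - 1)
        elif row["var_type"] == "deletion":
            first = min(row["del_positions"]) if row["del_positions"] else 0
            x = first / 10.0
        else:
            x = 0.0
        size = 1.0 + (math.log10(row["mean_freq"]) - math.log10(fmin))
        g.add_node(seq, x=x, y=y, size=size, var_type=row["var_type"],
                   mean_freq=float(row["mean_freq"]))
    nodes = list(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if is_single_indel_neighbor(a, b):
                g.add_edge(a, b)
    if reference_window is not None and reference_window in g:
        assert g.nodes[reference_window]["y"] == 0
    return g


def comparison_graph(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     min_freq: float = 1e-5, max_log_ratio: float = 3.0) -> nx.Graph:
    """Two-construct comparison: union of retained windows.

    ``color`` is the signed log10 ratio of mean frequencies (positive:
    enriched in A, capped at ``max_log_ratio``; a window absent from one
    table saturates); ``size`` derives from the larger mean frequency.
    """
    n_a = table_a.attrs.get("n_repeats", 1)
    n_b = table_b.attrs.get("n_repeats", 1)
    kept_a = table_a[[_passes_min_freq(r, n_a, min_freq) for _, r in table_a.iterrows()]]
    kept_b = table_b[[_passes_min_freq(r, n_b, min_freq) for _, r in table_b.iterrows()]]
    kept_a = kept_a[kept_a["var_type"] != "mixed"]
    kept_b = kept_b[kept_b["var_type"] != "mixed"]
    seqs = sorted(set(kept_a.index) | set(kept_b.index))
    if not seqs:
        return nx.Graph()
    means = {}
    for seq in seqs:
        fa = float(kept_a.loc[seq, "mean_freq"]) if seq in kept_a.index else 0.0
        fb = float(kept_b.loc[seq, "mean_freq"]) if seq in kept_b.index else 0.0
        means[seq] = (fa, fb)
    fmin = min(max(fa, fb) for fa, fb in means.values())
    g = nx.Graph()
    for seq in seqs:
        fa, fb = means[seq]
        row = kept_a.loc[seq] if seq in kept_a.index else kept_b.loc[seq]
        if fa > 0 and fb > 0:
            color = max(-max_log_ratio, min(max_log_ratio, math.log10(fa / fb)))
        else:
            color = max_log_ratio if fa > 0 else -max_log_ratio
        y = float(row["var_count"])
        if row["var_type"] == "deletion":
            y = -y
        x = 2.0 * _lex_fraction(row["ins_seq"]) - 1.0 if row["var_type"] == "insertion" else (
            (min(row["del_positions"]) / 10.0) if row["var_type"] == "deletion" and row["del_positions"] else 0.0)
        size = 1.0 + (math.log10(max(fa, fb)) - math.log10(fmin))
        g.add_node(seq, x=x, y=y, size=size, color=color, var_type=row["var_type"],
                   mean_freq_a=fa, mean_freq_b=fb)
    nodes = list(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if is_single_indel_neighbor(a, b):
                g.add_edge(a, b)
    return g


def position_histogram(table: pd.DataFrame, half: int = 10) -> pd.DataFrame:
    """Per-position variation frequency split by insertion/deletion.

    Deletion windows add their mean frequency to every deleted position bin;
    insertion windows add theirs once, at the insertion-point bin.  Bin
    labels are the signed relative positions -half..-1, +1..+half.
    """
    labels = [p for p in range(-half, half + 1) if p != 0]
    ins = {p: 0.0 for p in labels}
    dele = {p: 0.0 for p in labels}
    for _, row in table.iterrows():
        f = float(row["mean_freq"])
        if row["var_type"] in ("deletion", "mixed"):
            for p in row["del_positions"]:
                if p in dele:
                    dele[p] += f
        if row["var_type"] in ("insertion", "mixed") and row["ins_point"] is not None:
            p = row["ins_point"]
            if p in ins:
                ins[p] += f
    return pd.DataFrame({"position": labels,
                         "insertion_freq": [ins[p] for p in labels],
                         "deletion_freq": [dele[p] for p in labels]}).set_index("position")


def plot_graph(g: nx.Graph, path, title: str = "") -> None:
    """Static vector rendering of a variation-distance graph."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for a, b in g.edges:
        xa, ya = g.nodes[a]["x"], g.nodes[a]["y"]
        xb, yb = g.nodes[b]["x"], g.nodes[b]["y"]
        ax.plot([xa, xb], [ya, yb], color="0.7", lw=0.6, zorder=1)
    colors = {"none": "black", "insertion": "tab:orange", "deletion": "tab:blue", "mixed": "tab:gray"}
    for node, data in g.nodes(data=True):
        c = data.get("color")
        face = plt.cm.RdYlGn_r((c + 3) / 6) if c is not None else colors.get(data["var_type"], "gray")
        ax.scatter([data["x"]], [data["y"]], s=30 * data["size"], color=face, zorder=2,
                   edgecolors="black", linewidths=0.3)
    ax.set_xlabel("inserted-sequence order / first deleted position")
    ax.set_ylabel("signed variation count")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
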
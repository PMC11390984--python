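"""Microhomology pairs, deletion signatures and MMEJ detection.

A microhomology pair is two identical reference segments (here >= 3 bp), one
ending at or before the (upstream) cut and one starting at or after the
(downstream) cut, both inside the primer span and outside any excluded
interval.  Only *maximal* pairs are kept: extending both segments one base
left or one base right must break the identity.  Annealing of such a pair
deletes the downstream segment plus everything between the segments; the
junction-spanning *deletion signature* (10-nt upstream flank + segment +
10-nt downstream flank, flanks truncated at the primer boundaries) is an
exact substring of the repaired product but never of the intact reference,
so exact substring search over raw reads detects MMEJ products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CATEGORY_ABBREV = {
    "Exon1-Exon2": "EE2",
    "Exon2-Exon1": "EE1",
    "Exon1-Intron": "EI",
    "Exon2-Intron": "E2I",
    "Exon1-Exon1": "EE",
    "Exon2-Exon2": "E2E2",
    "Intron-Intron": "II",
    "mixed": "MX",
}


@dataclass(frozen=True)
class MHPair:
    name: str
    up_interval: tuple[int, int]
    down_interval: tuple[int, int]
    segment: str
    category: str
    strand_label: str = "forward"

    @property
    def deletion_interval(self) -> tuple[int, int]:
        """Reference interval removed by MMEJ via this pair (one segment kept)."""
        return (self.up_interval[1], self.down_interval[1])

    @property
    def deletion_size(self) -> int:
        s, e = self.deletion_interval
        return e - s


@dataclass(frozen=True)
class DeletionSignature:
    pair: MHPair
    sequence: str


def _interval_region(iv: tuple[int, int], regions: dict[str, tuple[int, int]]) -> str:
    """Region holding the larger part of the interval ('mixed' if none)."""
    best, best_ov = None, 0
    for rname, (s, e) in regions.items():
        ov = min(iv[1], e) - max(iv[0], s)
        if ov > best_ov:
            best, best_ov = rname, ov
    return best if best is not None else "mixed"


def _categorize(up: tuple[int, int], down: tuple[int, int], cut_up: int,
                regions: dict[str, tuple[int, int]]) -> str:
    r_up = _interval_region(up, regions)
    r_down = _interval_region(down, regions)
    # name by the region 5' of the cut first, then the region of the other segment
    r_cut = None
    for rname, (s, e) in regions.items():
        if s <= cut_up - 1 < e:
            r_cut = rname
            break
    if r_cut is None:
        r_cut = r_up
    other = r_down if r_up == r_cut else r_up
    return f"{r_cut}-{other}"


def enumerate_pairs(
    reference: str,
    cut_up: int,
    cut_down: int | None = None,
    regions: dict[str, tuple[int, int]] | None = None,
    excluded_intervals: dict[str, tuple[int, int]] | None = None,
    min_len: int = 3,
    primer_span: tuple[int, int] | None = None,
) -> list[MHPair]:
    """All maximal microhomology pairs flanking the cut(s).

    ``reference`` is the intact amplicon; all coordinates are amplicon
    coordinates.  ``cut_down`` defaults to ``cut_up`` (single cut).  The scan
    runs per segment offset: for offset d, equal-base runs between the
    sequence and itself shifted by d are exactly the maximal identical
    segment pairs at distance d (run boundaries break the identity on both
    sides simultaneously, which is the pairwise maximality rule).
    """
    if cut_down is None:
        cut_down = cut_up
    if cut_down < cut_up:
        raise ValueError("cut_down must be >= cut_up")
    ps, pe = primer_span if primer_span is not None else (0, len(reference))
    regions = regions or {}
    excl = list((excluded_intervals or {}).values())
    arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    n = len(arr)
    out: list[MHPair] = []
    for d in range(1, n):
        eq = arr[: n - d] == arr[d:]
        if not eq.any():
            continue
        # run starts/ends over the boolean equality vector
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            if e - s < min_len:
                continue
            up = (int(s), int(e))
            down = (int(s) + d, int(e) + d)
            if not (ps <= up[0] and up[1] <= cut_up):
                continue
            if not (cut_down <= down[0] and down[1] <= pe):
                continue
            if any(min(iv[1], b) > max(iv[0], a) for a, b in (up, down) for iv in excl):
                continue
            cat = _categorize(up, down, cut_up, regions) if regions else "mixed"
            out.append(MHPair("", up, down, reference[s:e], cat))
    out.sort(key=lambda p: (p.up_interval[0], p.down_interval[0]))
    # assign ordinal names per category, stable in genomic order
    counters: dict[str, int] = {}
    named = []
    for p in out:
        abbrev = CATEGORY_ABBREV.get(p.category, p.category)
        counters[abbrev] = counters.get(abbrev, 0) + 1
        named.append(MHPair(f"{abbrev}{counters[abbrev]}_{p.segment}", p.up_interval, p.down_interval, p.segment, p.category))
    return named


def build_signature(pair: MHPair, reference: str, primer_span: tuple[int, int] | None = None,
                    flank: int = 10) -> DeletionSignature:
    """Junction-spanning sequence identifying the MMEJ product of ``pair``."""
    ps, pe = primer_span if primer_span is not None else (0, len(reference))
    u0, u1 = pair.up_interval
    d0, d1 = pair.down_interval
    up_flank = reference[max(ps, u0 - flank): u0]
    down_flank = reference[d1: min(pe, d1 + flank)]
    return DeletionSignature(pair, up_flank + pair.segment + down_flank)


def detect_mmej(read: str, signatures: list[DeletionSignature]) -> set[str]:
    """Names of every pair whose deletion signature occurs exactly in ``read``."""
    return {sig.pair.name for sig in signatures if sig.sequence in read}


def mmej_frequencies(detections: list[set[str]], total_reads: int,
                     pairs: list[MHPair] | None = None) -> dict:
    """Per-pair and per-category MMEJ frequencies over a library.

    A read matching several signatures counts once per pair but once in the
    MMEJ total.  Denominator: total reads in the library.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    per_pair: dict[str, int] = {}
    any_count = 0
    for det in detections:
        if det:
            any_count += 1
        for name in det:
            per_pair[name] = per_pair.get(name, 0) + 1
    freq = {name: c / total_reads for name, c in sorted(per_pair.items())}
    result = {"per_pair": freq, "mmej_total": any_count / total_reads}
    if pairs is not None:
        cat_of = {p.name: p.category for p in pairs}
        by_cat: dict[str, float] = {}
        for name, f in freq.items():
            cat = cat_of.get(name, "unknown")
            by_cat[cat] = by_cat.get(cat, 0.0) + f
        exon_exon = sum(f for c, f in by_cat.items() if "Intron" not in c)
        exon_intron = sum(f for c, f in by_cat.items() if "Intron" in c)
        result["per_category"] = by_cat
        result["exon_exon_total"] = exon_exon
        result["exon_intron_total"] = exon_intron
    return result


def pair_catalog_rows(pairs: list[MHPair], reference: str,
                      primer_span: tuple[int, int] | None = None) -> list[dict]:
    """Flat rows (TSV-ready) for a pair catalog including signatures."""
    rows = []
    for p in pairs:
        sig = build_signature(p, reference, primer_span)
        rows.append(
            {
                "name": p.name,
                "up_start": p.up_interval[0],
                "up_end": p.up_interval[1],
                "down_start": p.down_interval[0],
                "down_end": p.down_interval[1],
                "segment": p.segment,
                "category": p.category,
                "signature": sig.sequence,
            }
        )
    return rows
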
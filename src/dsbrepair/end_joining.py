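"""Alignment to the repair reference and NHEJ / error-free classification.

Reads are aligned semi-globally: the read start is pinned to reference
position 0 (reads begin at the sequencing primer) and the read 3' end is
free (the fragment may extend past the 150-nt read).  The candidate path
comes from edlib; the accept/reject contract is evaluated on the parsed
operation runs with an affine-style score (match +1, mismatch -1, gap run
-5 open -1/base).  Reads are rejected when alignment fails, when the first
reference base is unaligned, or when the score falls below half the read
length (a floor calibrated so shuffled sequence is always rejected).

Because end-joining junctions are ambiguous wherever the broken ends share
sequence, the aligner's in/del placement is then *canonicalised*: a
candidate alignment is constructed in which every in/del base forms one
consecutive block adjacent to or spanning the cut, scanning all block
placements that touch the cut, and the candidate replaces the original iff
its mismatch count does not increase.  A read whose final alignment has all
in/dels in one cut-encapsulating block is an NHEJ in/del product (or
error-free/uncut when there are none); substitutions are ignored throughout
as sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import edlib
import numpy as np

from Bio import Align

# op kinds: ("M", ref_start, length) match, ("X", ref_start, length) mismatch,
# ("I", ref_pos, inserted_seq), ("D", ref_start, length) deletion
Op = tuple


@dataclass
class Alignment:
    read_id: str
    read: str
    ops: list[Op]
    encapsulating: bool = False

    @property
    def n_mismatch(self) -> int:
        return sum(op[2] for op in self.ops if op[0] == "X")

    @property
    def n_indel_runs(self) -> int:
        return sum(1 for op in self.ops if op[0] in "ID")

    @property
    def indel_ops(self) -> list[Op]:
        return [op for op in self.ops if op[0] in "ID"]

    @property
    def ref_end(self) -> int:
        return _ref_end(self.ops)


def _ref_end(ops: list[Op]) -> int:
    end = 0
    for kind, pos, payload in ops:
        if kind in "MXD":
            end = pos + (payload if isinstance(payload, int) else len(payload))
        else:
            end = max(end, pos)
    return end


@dataclass(frozen=True)
class Reject:
    read_id: str
    reason: str


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _ops_from_cigar(cigar: str, read: str, ref: str) -> list[Op]:
    ops: list[Op] = []
    r = q = 0
    for num, kind in _CIGAR_RE.findall(cigar):
        n = int(num)
        if kind == "=":
            ops.append(("M", r, n)); r += n; q += n
        elif kind == "X":
            ops.append(("X", r, n)); r += n; q += n
        elif kind == "I":
            ops.append(("I", r, read[q:q + n])); q += n
        elif kind == "D":
            ops.append(("D", r, n)); r += n
    return _merge_ops(ops)


def _merge_ops(ops: list[Op]) -> list[Op]:
    merged: list[Op] = []
    for op in ops:
        if merged and merged[-1][0] == op[0]:
            k, pos, payload = merged[-1]
            if k in "MXD":
                merged[-1] = (k, pos, payload + op[2])
                continue
            if k == "I" and op[1] == pos:
                merged[-1] = (k, pos, payload + op[2])
                continue
        merged.append(op)
    return merged


MISMATCH_PENALTY = 4  # heavier than a 1-nt gap extension, as in short-read
GAP_OPEN = 5           # aligners, so one small in/del beats two substitutions
GAP_EXTEND = 1


def alignment_score(ops: list[Op]) -> int:
    """Affine-style score of an op list (match +1, mismatch -4, gap -5-1/nt)."""
    score = 0
    for kind, _pos, payload in ops:
        n = payload if isinstance(payload, int) else len(payload)
        if kind == "M":
            score += n
        elif kind == "X":
            score -= MISMATCH_PENALTY * n
        else:
            score -= GAP_OPEN + GAP_EXTEND * n
    return score


def align_to_reference(read: str, reference: str, read_id: str = "",
                       score_floor_frac: float = 0.5) -> Alignment | Reject:
    """Semi-global alignment anchored at reference position 0."""
    if not read:
        return Reject(read_id, "empty")
    if reference.startswith(read):
        return Alignment(read_id, read, [("M", 0, len(read))])
    res = edlib.align(read, reference, task="path", mode="SHW")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return Reject(read_id, "unaligned")
    ops = _ops_from_cigar(res["cigar"], read, reference)
    # a unit-cost edit path may represent substitutions as in/del pairs on
    # ties; an affine-gap aligner prefers the substitution representation,
    # so adopt it whenever it scores at least as well
    if len(read) <= len(reference) and any(op[0] in "ID" for op in ops):
        sub_ops = _runs_from_compare(read, reference, 0)
        if alignment_score(sub_ops) >= alignment_score(ops):
            ops = sub_ops
    if ops[0][0] == "D":
        return Reject(read_id, "not_anchored")
    if alignment_score(ops) < score_floor_frac * len(read):
        return Reject(read_id, "score_floor")
    return Alignment(read_id, read, ops)


def _runs_from_compare(read_slice: str, ref: str, ref_start: int) -> list[Op]:
    """Match/mismatch runs of read_slice against ref starting at ref_start."""
    ops: list[Op] = []
    i = 0
    n = len(read_slice)
    while i < n:
        kind = "M" if read_slice[i] == ref[ref_start + i] else "X"
        j = i + 1
        while j < n and ("M" if read_slice[j] == ref[ref_start + j] else "X") == kind:
            j += 1
        ops.append((kind, ref_start + i, j - i))
        i = j
    return ops


def _is_encapsulating(ops: list[Op], cut: int) -> bool:
    """True iff all in/dels form one consecutive block touching the cut."""
    idx = [i for i, op in enumerate(ops) if op[0] in "ID"]
    if not idx:
        return True
    if idx != list(range(idx[0], idx[-1] + 1)):
        return False
    positions = []
    for i in idx:
        kind, pos, payload = ops[i]
        if kind == "D":
            positions.append((pos, pos + payload))
        else:
            positions.append((pos, pos))
    lo = min(p[0] for p in positions)
    hi = max(p[1] for p in positions)
    return lo <= cut <= hi


def _best_block_placement(read: str, reference: str, cut: int,
                          ins_len: int, del_len: int) -> tuple[int, int] | None:
    """Best (mismatches, a) for one in/del block of the given shape at the cut.

    The block inserts ``ins_len`` read bases and deletes ``del_len``
    reference bases at reference position ``a``, with the deletion required
    to touch or span the cut (a pure insertion sits exactly at the cut).
    Returns None when no placement fits.
    """
    ra = np.frombuffer(read.encode(), dtype=np.uint8)
    fa = np.frombuffer(reference.encode(), dtype=np.uint8)
    nr, nf = len(ra), len(fa)
    lp = min(nr, nf)
    pref = np.zeros(lp + 1, dtype=np.int32)
    np.cumsum(ra[:lp] != fa[:lp], out=pref[1:])
    shift = del_len - ins_len
    if nr + shift > nf:
        return None
    tail = np.zeros(nr + 1, dtype=np.int32)
    j0 = max(0, -shift)  # smallest read index with a valid reference partner
    if nr > j0:
        mism = (ra[j0:] != fa[j0 + shift: nr + shift]).astype(np.int32)
        tail[j0:nr] = mism[::-1].cumsum()[::-1]
    if del_len > 0:
        a_lo = max(0, cut - del_len)
        a_hi = min(cut, nf - del_len, nr - ins_len, lp)
    elif ins_len > 0:
        a_lo = a_hi = cut
        if cut > min(nr - ins_len, lp, nf):
            return None
    else:  # substitution-only representation: placement is irrelevant
        a_lo = a_hi = min(cut, nr, lp)
    best = None
    for a in range(a_lo, a_hi + 1):
        mm = int(pref[a]) + int(tail[min(max(a + ins_len, j0), nr)])
        key = (mm, abs(2 * a + del_len - 2 * cut), a)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[0], best[2]


def _block_ops(read: str, reference: str, a: int, ins_len: int, del_len: int) -> list[Op]:
    ops: list[Op] = list(_runs_from_compare(read[:a], reference, 0))
    if ins_len:
        ops.append(("I", a, read[a:a + ins_len]))
    if del_len:
        ops.append(("D", a, del_len))
    shift = del_len - ins_len
    t0 = a + ins_len
    i = t0
    while i < len(read):
        kind = "M" if read[i] == reference[i + shift] else "X"
        j = i + 1
        while j < len(read) and ("M" if read[j] == reference[j + shift] else "X") == kind:
            j += 1
        ops.append((kind, i + shift, j - i))
        i = j
    return _merge_ops(ops)


def realign_encapsulate(aln: Alignment, reference: str, cut: int) -> Alignment:
    """Canonicalise in/del placement into one block at the cut.

    Candidate alignments place all in/del bases as one consecutive block
    adjacent to or spanning the cut, both with the original alignment's
    insertion/deletion totals and with the *minimal* structure realising the
    same net length change (an edit path of unit costs may represent a
    substitution as an insertion+deletion pair, which an affine-gap aligner
    would never do).  The best candidate replaces the original alignment iff
    its mismatch count does not increase or its affine-style score does not
    decrease.  The returned alignment carries the ``encapsulating`` flag.
    """
    read = aln.read
    indels = aln.indel_ops
    if not indels:
        aln.encapsulating = True
        return aln
    ins_len = sum(len(op[2]) for op in indels if op[0] == "I")
    del_len = sum(op[2] for op in indels if op[0] == "D")
    net = ins_len - del_len
    # candidate block shapes: any sub-total of the path's in/del bases (a
    # unit-cost edit path may encode substitutions or free-end slippage as
    # spurious in/del pairs that an affine-gap aligner would not emit)
    if (ins_len + 1) * (del_len + 1) <= 400:
        structures = {(i, d) for i in range(ins_len + 1) for d in range(del_len + 1)}
    else:
        structures = {(ins_len, del_len), (max(net, 0), max(-net, 0)),
                      (0, 0), (ins_len, 0), (0, del_len)}
    orig_mm = aln.n_mismatch

    best = None  # keyed by (mm, score desc, fewer indel bases, a)
    for i_len, d_len in structures:
        placed = _best_block_placement(read, reference, cut, i_len, d_len)
        if placed is None:
            continue
        mm, a = placed
        matches = len(read) - i_len - mm
        score = matches - MISMATCH_PENALTY * mm
        if i_len:
            score -= GAP_OPEN + GAP_EXTEND * i_len
        if d_len:
            score -= GAP_OPEN + GAP_EXTEND * d_len
        key = (mm, -score, i_len + d_len, a)
        if best is None or key < best[0]:
            best = (key, mm, score, i_len, d_len, a)
    if best is not None:
        _, mm, _score, i_len, d_len, a = best
        if mm <= orig_mm:  # the acceptance rule: mismatches may not increase
            aln = Alignment(aln.read_id, read, _block_ops(read, reference, a, i_len, d_len))
    aln.encapsulating = _is_encapsulating(aln.ops, cut)
    return aln


# -- 1-DSB classification --------------------------------------------------

CATEGORIES_1DSB = (
    "error_free_uncut",
    "nhej_indel",
    "mmej",
    "rejected_short",
    "rejected_unaligned",
    "rejected_not_encapsulating",
)


@dataclass
class ReadCall:
    read_id: str
    category: str
    pairs: frozenset = frozenset()
    overlap_nhej: bool = False   # MMEJ read that also satisfies the NHEJ rule
    aln: Alignment | None = None


def classify_read_1dsb(read_id: str, read: str, reference: str, cut: int,
                       min_len: int, signatures, check_overlap: bool = True) -> ReadCall:
    """Full per-read flow: MMEJ signature scan on the raw read, then length
    filter, alignment, realignment, and the NHEJ/error-free split."""
    from .microhomology import detect_mmej

    hits = detect_mmej(read, signatures)
    aln = None
    alignment_cat = None
    if len(read) >= min_len or (hits and check_overlap):
        res = align_to_reference(read, reference, read_id)
        if isinstance(res, Alignment):
            aln = realign_encapsulate(res, reference, cut)
            if not aln.indel_ops:
                alignment_cat = "error_free_uncut"
            elif aln.encapsulating:
                alignment_cat = "nhej_indel"
            else:
                alignment_cat = "rejected_not_encapsulating"
        else:
            alignment_cat = "rejected_unaligned"
    if hits:
        overlap = check_overlap and len(read) >= min_len and alignment_cat in ("nhej_indel", "error_free_uncut")
        return ReadCall(read_id, "mmej", frozenset(hits), overlap, aln)
    if len(read) < min_len:
        return ReadCall(read_id, "rejected_short")
    return ReadCall(read_id, alignment_cat, aln=aln)


def classify_library_1dsb(reads: list[tuple[str, str]], reference: str, cut: int,
                          signatures, min_len: int = 130) -> tuple[list[ReadCall], dict[str, float]]:
    """Classify a barcode-accepted library; frequencies over all input reads."""
    calls = [classify_read_1dsb(rid, seq, reference, cut, min_len, signatures) for rid, seq in reads]
    n = len(calls)
    summary = {cat: 0 for cat in CATEGORIES_1DSB}
    overlap = 0
    for c in calls:
        summary[c.category] += 1
        if c.overlap_nhej:
            overlap += 1
    freqs = {cat: cnt / n for cat, cnt in summary.items()} if n else {}
    if n:
        freqs["mmej_nhej_overlap"] = overlap / n
    return calls, freqs


# -- audit of unclassified reads ------------------------------------------

_audit_aligner = None


def _get_audit_aligner() -> Align.PairwiseAligner:
    global _audit_aligner
    if _audit_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -5
        a.extend_gap_score = -1
        try:  # the read (target) 3' end is free
            a.open_right_insertion_score = 0
            a.extend_right_insertion_score = 0
        except AttributeError:
            a.target_right_open_gap_score = 0
            a.target_right_extend_gap_score = 0
        _audit_aligner = a
    return _audit_aligner


def audit_unclassified(read: str, reference: str, cut: int,
                       regions: dict[str, tuple[int, int]],
                       excluded: dict[str, tuple[int, int]] | None = None,
                       shift_tolerance: int = 3) -> str:
    """Subcategorise a read left out of all primary groups.

    Uses a general pairwise aligner (independent of the semi-global pipeline
    aligner), then inspects the in/del geometry: a single in/del block within
    ``shift_tolerance`` nt of the cut is a shifted end-joining product; a
    deletion touching the cut is labelled by the regions holding its two
    endpoints (exon-exon / exon-intron / exon-branch); anything else is
    ``other``.
    """
    aligner = _get_audit_aligner()
    try:
        best = aligner.align(read, reference)[0]
    except Exception:
        return "other"
    # Bio.Align aligned blocks: paired (read, ref) coordinate segments
    read_blocks, ref_blocks = best.aligned
    indels: list[tuple[str, int, int]] = []  # (kind, ref_start, ref_end)
    for i in range(1, len(ref_blocks)):
        rgap = ref_blocks[i][0] - ref_blocks[i - 1][1]
        qgap = read_blocks[i][0] - read_blocks[i - 1][1]
        if rgap > 0:
            indels.append(("D", int(ref_blocks[i - 1][1]), int(ref_blocks[i][0])))
        if qgap > 0:
            p = int(ref_blocks[i - 1][1])
            indels.append(("I", p, p))
    if not indels:
        return "other"
    lo = min(s for _, s, _ in indels)
    hi = max(e for _, _, e in indels)
    dist = 0 if lo <= cut <= hi else min(abs(cut - lo), abs(cut - hi))
    if 0 < dist <= shift_tolerance:
        return "shifted_le3"
    dels = [iv for iv in indels if iv[0] == "D"]
    if dels and lo <= cut <= hi:
        d_start = min(s for _, s, _ in dels)
        d_end = max(e for _, _, e in dels)
        for name, (bs, be) in (excluded or {}).items():
            if "branch" in name.lower() and (bs <= d_start < be or bs <= d_end - 1 < be):
                return "exon_branch_del"

        def region_of(p):
            for rname, (s, e) in regions.items():
                if s <= p < e:
                    return rname
            return None

        r1, r2 = region_of(d_start), region_of(d_end - 1)
        if r1 and r2:
            if r1.startswith("Exon") and r2.startswith("Exon"):
                return "exon_exon_del"
            if "Intron" in (r1, r2) and (r1.startswith("Exon") or r2.startswith("Exon")):
                return "exon_intron_del"
    return "other"
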
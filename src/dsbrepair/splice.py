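"""Splicing-status classification of cDNA amplicon reads.

A read aligned to the genomic construct reference shows splicing as a long
reference gap (here: any deletion run of at least ``min_gap`` nt, default
20, which separates splice events from end-joining in/dels).  Reads with no
event are non-spliced; an event whose gap length equals the intron length
is the canonical spliced transcript; events over other GT..AG intervals are
alternative splicing; remaining events are non-canonical.  Reads the
aligner rejects are 'unaligned'.
"""

from __future__ import annotations

from .end_joining import Alignment, align_to_reference

SPLICE_CATEGORIES = ("spliced", "non_spliced", "alt_spliced", "non_canonical_alt", "unaligned")


def splice_events_from_ops(ops, min_gap: int = 20) -> list[tuple[int, int]]:
    """(ref_start, length) of every reference gap >= min_gap."""
    return [(pos, ln) for kind, pos, ln in ops if kind == "D" and ln >= min_gap]


def align_spliced(read: str, reference: str, min_gap: int = 20) -> Alignment | None:
    """Splice-aware anchored alignment with at most one long reference gap.

    A splice gap must be cheap regardless of its length (a general edit
    aligner prefers a run of mismatches over a long gap), so the read is
    aligned as reference prefix + optional gap of any length >= ``min_gap``
    + reference suffix, anchored at reference position 0 with the read 3'
    end free.  Among placements minimising mismatches, canonical GT..AG
    gap boundaries are preferred (the tie-break splice aligners use).
    Returns None when even the best model leaves the read unrecognisable
    (matched minus mismatched bases below half the read length).
    """
    import numpy as np

    ra = np.frombuffer(read.encode(), dtype=np.uint8)
    fa = np.frombuffer(reference.encode(), dtype=np.uint8)
    nr, nf = len(ra), len(fa)
    if nr == 0 or nr > nf:
        return None
    pref = np.zeros(nr + 1, dtype=np.int32)
    np.cumsum(ra != fa[:nr], out=pref[1:])
    mm_contig = int(pref[nr])
    best = None  # (mm, non_canonical, gap, a)
    for g in range(min_gap, nf - nr + 1):
        mism = (ra != fa[g: g + nr]).astype(np.int32)
        tail = np.zeros(nr + 1, dtype=np.int32)
        tail[:nr] = mism[::-1].cumsum()[::-1]
        mmvec = pref + tail
        mm = int(mmvec.min())
        if best is not None and mm > best[0]:
            continue
        ties = np.nonzero(mmvec == mm)[0]
        a = int(ties[0])
        canonical = 1
        for t in ties:
            if reference[t:t + 2] == "GT" and reference[t + g - 2:t + g] == "AG":
                a, canonical = int(t), 0
                break
        key = (mm, canonical, g, a)
        if best is None or key < best:
            best = key
    # a gapped model must beat the contiguous one by more than 2 mismatches
    if best is not None and best[0] + 2 < mm_contig:
        mm, _canon, g, a = best
    else:
        mm, g, a = mm_contig, 0, nr
    if nr - 2 * mm < 0.5 * nr:  # matched minus mismatched floor
        return None
    from .end_joining import _merge_ops, _runs_from_compare
    ops = list(_runs_from_compare(read[:a], reference, 0))
    if g:
        ops.append(("D", a, g))
        i = a
        while i < nr:
            kind = "M" if read[i] == reference[i + g] else "X"
            j = i + 1
            while j < nr and ("M" if read[j] == reference[j + g] else "X") == kind:
                j += 1
            ops.append((kind, i + g, j - i))
            i = j
    return Alignment("", read, _merge_ops(ops))


def classify_transcript_read(read: str, reference: str, intron_interval: tuple[int, int],
                             min_gap: int = 20, positional: bool = False) -> str:
    """Splice category of one cDNA read against the genomic reference.

    ``positional=True`` additionally requires the canonical event to start
    at the annotated intron start (stricter than gap-length equality).
    """
    res = align_spliced(read, reference, min_gap)
    if res is None:
        return "unaligned"
    return classify_from_alignment(res, reference, intron_interval, min_gap, positional)


def classify_from_alignment(aln: Alignment, reference: str, intron_interval: tuple[int, int],
                            min_gap: int = 20, positional: bool = False) -> str:
    events = splice_events_from_ops(aln.ops, min_gap)
    if not events:
        return "non_spliced"
    i0, i1 = intron_interval
    intron_len = i1 - i0
    for pos, ln in events:
        if ln == intron_len and (not positional or pos == i0):
            return "spliced"
    if all(reference[pos:pos + 2] == "GT" and reference[pos + ln - 2:pos + ln] == "AG"
           for pos, ln in events):
        return "alt_spliced"
    return "non_canonical_alt"


def classify_sam(path: str, reference: str, intron_interval: tuple[int, int],
                 min_gap: int = 20) -> dict[str, float]:
    """Category frequencies from a splice-aware aligner's SAM output.

    N (skipped-region) and D cigar operations both count as reference gaps.
    """
    import pysam

    counts = {c: 0 for c in SPLICE_CATEGORIES}
    n = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            n += 1
            if rec.is_unmapped:
                counts["unaligned"] += 1
                continue
            events = []
            ref_pos = rec.reference_start
            for op, ln in rec.cigartuples or []:
                if op in (2, 3):  # D or N
                    if ln >= min_gap:
                        events.append((ref_pos, ln))
                    ref_pos += ln
                elif op in (0, 7, 8):  # M / = / X
                    ref_pos += ln
            cat = _categorize_events(events, reference, intron_interval)
            counts[cat] += 1
    return {c: (counts[c] / n if n else 0.0) for c in SPLICE_CATEGORIES}


def _categorize_events(events, reference, intron_interval):
    if not events:
        return "non_spliced"
    i0, i1 = intron_interval
    for pos, ln in events:
        if ln == i1 - i0:
            return "spliced"
    if all(reference[pos:pos + 2] == "GT" and reference[pos + ln - 2:pos + ln] == "AG"
           for pos, ln in events):
        return "alt_spliced"
    return "non_canonical_alt"


def classify_library(reads: list[tuple[str, str]], reference: str,
                     intron_interval: tuple[int, int], min_gap: int = 20) -> dict[str, float]:
    """Category frequencies over a cDNA library (frequencies sum to 1)."""
    counts = {c: 0 for c in SPLICE_CATEGORIES}
    for _rid, seq in reads:
        counts[classify_transcript_read(seq, reference, intron_interval, min_gap)] += 1
    n = len(reads)
    return {c: (counts[c] / n if n else 0.0) for c in SPLICE_CATEGORIES}
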
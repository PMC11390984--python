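"""Classification of double-cut (double-strand gap) repair products.

With two cuts flanking the intron the main outcomes separate by product
length: intact or religated molecules keep the intron and read out at the
full read length, while pop-out products collapse to the gap-repaired
length.  Reads longer than the length threshold (default 130 nt, strict
inequality) are therefore *with intron*; shorter reads are pop-out products,
split into MMEJ (exact deletion-signature match, checked first) and NHEJ
(everything else).  Flipped re-insertion of the excised segment is measured
independently with a 20-nt probe from the flipped reference, taken a fixed
offset inside the primer-proximal cut so that it falls within the read; the
probe is required to be absent from the intact and gap-repaired references.

For gaps internal to an exon the length rule is replaced by best-of-three
alignment against the intact / gap-repaired / flipped references; for yeast
constructs, whose amplicons all exceed the read length, intron status is
called by the presence of any 20-mer of the 3' exon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .end_joining import Alignment, align_to_reference
from .microhomology import DeletionSignature, detect_mmej
from .reference_model import ConstructSpec, ConstructError, derive_references, revcomp

GAP_CATEGORIES = ("with_intron_retained", "popout_nhej", "popout_mmej", "segment_retention", "unclassified")


def classify_by_length(read: str, threshold: int = 130) -> str:
    """'with_intron' iff the read is strictly longer than the threshold."""
    return "with_intron" if len(read) > threshold else "short"


def classify_short_read(read: str, signatures: list[DeletionSignature]) -> tuple[str, frozenset]:
    """Pop-out products: MMEJ by exact signature first, otherwise NHEJ."""
    hits = detect_mmej(read, signatures)
    if hits:
        return "popout_mmej", frozenset(hits)
    return "popout_nhej", frozenset()


def make_flip_probe(construct: ConstructSpec, cut_a: str, cut_b: str,
                    offset: int = 10, k: int = 20) -> str:
    """Diagnostic probe for flipped-segment insertion.

    The probe is the k-mer of the *flipped* reference beginning ``offset``
    nt downstream of the upstream cut, i.e. the reverse complement of the
    segment's far end, placed so it is captured near the start of the read.
    Raises if the probe also occurs in the intact or gap-repaired reference
    (it would not be diagnostic).
    """
    refs = derive_references(construct, cut_a, cut_b)
    ca = refs.cut_in_ref1
    probe = refs.ref_flipped[ca + offset: ca + offset + k]
    if len(probe) < k:
        raise ConstructError(f"cut_sites: flipped segment too short for a {k}-nt probe at offset {offset}")
    if probe in refs.ref_1dsb or probe in refs.ref_2dsb:
        raise ConstructError("cut_sites: flip probe occurs in an unbroken reference; not diagnostic")
    return probe


def detect_flipped(read: str, probe: str) -> bool:
    return probe in read


def classify_three_refs(read: str, refs: dict[str, str],
                        signatures: list[DeletionSignature],
                        score_floor_frac: float = 0.5) -> tuple[str, bool]:
    """Exon-internal gaps: best-scoring of {no_dsb, gap_repair, flipped} wins.

    Returns ``(category, flipped_hit)``; intact and flipped winners are
    both reported as segment retention, with flipped winners additionally
    flagged for the flip-frequency tally.  An MMEJ signature match overrides
    a gap-repair winner.
    """
    for key in ("no_dsb", "gap_repair", "flipped"):
        if key not in refs:
            raise ValueError(f"refs must provide {key!r}")
    best_key, best_score = None, None
    for key in ("no_dsb", "gap_repair", "flipped"):
        res = align_to_reference(read, refs[key], score_floor_frac=score_floor_frac)
        if isinstance(res, Alignment):
            from .end_joining import alignment_score
            score = alignment_score(res.ops)
            if best_score is None or score > best_score:
                best_key, best_score = key, score
    if best_key is None:
        return "unclassified", False
    if best_key == "gap_repair":
        hits = detect_mmej(read, signatures)
        return ("popout_mmej" if hits else "popout_nhej"), False
    return "segment_retention", best_key == "flipped"


def yeast_intron_status(read: str, exon3_seq: str, k: int = 20) -> str:
    """'intron_lost' iff the read contains any k-mer of the 3' exon."""
    if len(exon3_seq) < k:
        raise ValueError(f"3' exon shorter than {k} nt")
    kmers = {exon3_seq[i:i + k] for i in range(len(exon3_seq) - k + 1)}
    for i in range(len(read) - k + 1):
        if read[i:i + k] in kmers:
            return "intron_lost"
    return "intron_retained"


def rtdr_scan(reads: list[str], spliced_probe: str) -> float:
    """Fraction of reads containing the exact spliced-product sequence.

    ``spliced_probe`` is the junction-spanning portion of the spliced
    transcript (DNA alphabet) that fits within the read capture range; any
    mismatch defeats the exact search.
    """
    if not reads:
        return 0.0
    return sum(1 for r in reads if spliced_probe in r) / len(reads)


@dataclass
class GapCall:
    read_id: str
    category: str
    pairs: frozenset = frozenset()
    flipped: bool = False


def classify_library_2dsb(reads: list[tuple[str, str]],
                          signatures: list[DeletionSignature],
                          flip_probe: str | None = None,
                          length_threshold: int = 130) -> tuple[list[GapCall], dict[str, float]]:
    """Length-rule classification of a barcode-accepted 2-DSB library.

    Frequencies are over all input reads; the flipped-insertion frequency is
    reported as a separate, overlapping tally (flipped molecules retain the
    segment and therefore also count as with-intron).
    """
    calls = []
    for rid, seq in reads:
        if classify_by_length(seq, length_threshold) == "with_intron":
            cat, pairs = "with_intron_retained", frozenset()
        else:
            cat, pairs = classify_short_read(seq, signatures)
        flipped = bool(flip_probe) and detect_flipped(seq, flip_probe)
        calls.append(GapCall(rid, cat, pairs, flipped))
    n = len(calls)
    freqs: dict[str, float] = {}
    if n:
        for cat in ("with_intron_retained", "popout_nhej", "popout_mmej"):
            freqs[cat] = sum(1 for c in calls if c.category == cat) / n
        freqs["flipped"] = sum(1 for c in calls if c.flipped) / n
    return calls, freqs
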
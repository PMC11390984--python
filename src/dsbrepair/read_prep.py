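"""Read trimming and barcode verification.

Library fragments carry a 6-nt tag at each end: NN + a 4-nt library code at
the 5' end, and the mirror-image tag at the 3' end (code + NN).  Acceptance
requires the first 12 nt of a forward read to be NN + code + the first six
reference nucleotides.  The 3' tag may fall outside a 150-nt read, so for
reads longer than the length gate (default 140 nt) whose last 12 nt do not
contain the last six reference nucleotides the 3' check is skipped;
otherwise the read must end with last-six + code + NN.  Accepted reads are
returned with all tag bases stripped, beginning with the reference hexamer.

Reverse-strand reads are the reverse complement of the fragment and are
checked symmetrically (revcomp of the last hexamer at the 5' end, revcomp of
the first at the 3' end), then reverse-complemented to forward orientation
so every downstream classifier sees forward sequence only.

The quality/adapter trimmer is a built-in minimal implementation (3' adapter
removed at >=90 % identity overlap, then 3' bases below Q20 trimmed); any
externally pre-trimmed FASTQ can be fed in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference_model import revcomp

ILLUMINA_ADAPTER = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class BarcodeScheme:
    code: str                 # 4-nt library code (the XXXX)
    ref_first6: str           # first 6 nt of the forward reference
    ref_last6: str            # last 6 nt of the forward reference
    length_gate: int = 140
    code3: str | None = None  # 3' code; defaults to `code`

    def __post_init__(self):
        for fname, val, n in (("code", self.code, 4), ("ref_first6", self.ref_first6, 6), ("ref_last6", self.ref_last6, 6)):
            if len(val) != n or set(val) - set("ACGTN"):
                raise ValueError(f"{fname}: expected {n}-nt DNA string, got {val!r}")

    @property
    def code_3prime(self) -> str:
        return self.code3 if self.code3 is not None else self.code


def trim_quality_adapter(seq: str, qual: str, adapter: str = ILLUMINA_ADAPTER,
                         q_threshold: int = 20, min_overlap: int = 3,
                         min_identity: float = 0.9) -> tuple[str, str]:
    """3' adapter and quality trimming; never lengthens a read."""
    n = len(seq)
    cut = n
    for i in range(n):  # leftmost adapter occurrence as a read suffix
        olen = min(n - i, len(adapter))
        if olen < min_overlap:
            break
        window = seq[i:i + olen]
        matches = sum(a == b for a, b in zip(window, adapter))
        if matches >= min_identity * olen:
            cut = i
            break
    seq, qual = seq[:cut], qual[:cut]
    while seq and ord(qual[-1]) - 33 < q_threshold:
        seq, qual = seq[:-1], qual[:-1]
    return seq, qual


def verify_strip_barcodes(read: str, scheme: BarcodeScheme,
                          strand: str = "forward") -> tuple[str | None, str]:
    """Barcode verification and stripping.

    Returns ``(stripped_forward_sequence, "ok")`` on acceptance or
    ``(None, reason)`` on rejection; reverse-strand reads are returned
    reverse-complemented to forward orientation.
    """
    if strand not in ("forward", "reverse"):
        raise ValueError(f"strand: {strand!r}")
    if len(read) < 12:
        return None, "too_short"
    if strand == "forward":
        first6, last6 = scheme.ref_first6, scheme.ref_last6
        code5, code3 = scheme.code, scheme.code_3prime
    else:
        # the reverse read is the revcomp of the fragment, so hexamers and
        # codes appear reverse-complemented and swapped end-for-end
        first6, last6 = revcomp(scheme.ref_last6), revcomp(scheme.ref_first6)
        code5, code3 = revcomp(scheme.code_3prime), revcomp(scheme.code)
    head = read[:12]
    if head[2:6] != code5 or head[6:12] != first6:
        return None, "barcode_mismatch"
    stripped = read[6:]
    tail = read[-12:]
    if len(read) > scheme.length_gate and last6 not in tail:
        pass  # 3' tag fell outside the read; check skipped
    else:
        if tail[:6] != last6 or tail[6:10] != code3:
            return None, "barcode_mismatch_3p"
        stripped = stripped[:-6]
    if strand == "reverse":
        stripped = revcomp(stripped)
    return stripped, "ok"


def prepare_library(records: list[tuple[str, str, str]], scheme: BarcodeScheme,
                    strand: str = "forward", trim: bool = True) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Trim + verify a library of ``(read_id, seq, qual)`` records.

    Returns accepted ``(read_id, forward_sequence)`` pairs and a counter of
    rejection reasons (including ``ok``).
    """
    accepted: list[tuple[str, str]] = []
    tally: dict[str, int] = {}
    for read_id, seq, qual in records:
        if trim:
            seq, qual = trim_quality_adapter(seq, qual)
        if not seq:
            tally["empty"] = tally.get("empty", 0) + 1
            continue
        stripped, reason = verify_strip_barcodes(seq, scheme, strand)
        tally[reason] = tally.get(reason, 0) + 1
        if stripped is not None:
            accepted.append((read_id, stripped))
    return accepted, tally
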
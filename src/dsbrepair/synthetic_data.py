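"""Synthetic constructs and amplicon read libraries with known ground truth.

The generator emulates the study design: a two-exon reporter whose intron
(starting GT, ending AG, with a marked branch-site interval) can be excised
between two Cas9 cuts, sequenced as barcoded 150-nt amplicon reads.  Each
simulated read is one repair product — error-free/uncut, NHEJ in/del at the
cut, MMEJ between a chosen microhomology pair, intron pop-out (with optional
junction in/del), flipped-segment re-insertion, an RNA-identical spliced
product, or unalignable noise — wrapped in the NN+code barcode scheme,
truncated to the read length, and subjected to a flat per-base substitution
error.  A truth record per read gives every downstream stage an oracle.

Event fractions are drawn by inverse-CDF over the mix in sorted kind order
from a single generator seeded per call, so identical seeds give
byte-identical libraries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .microhomology import MHPair, enumerate_pairs
from .read_prep import BarcodeScheme
from .reference_model import ConstructSpec, ConstructError, derive_flipped_reference, with_branch_deleted

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EventMix:
    fractions: dict[str, float]
    sub_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total})")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if not (0.0 <= self.sub_error_rate <= 0.1):
            raise ValueError("sub_error_rate must lie in [0, 0.1]")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    true_event: str
    details: str = ""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, n)]).decode()


def make_construct(
    seed: int,
    exon1_len: int = 59,
    intron_len: int = 111,
    exon2_len: int = 59,
    branch_deleted: bool = False,
    branch_len: int = 55,
    cut_offset_a: int = 0,
    cut_offset_b: int = 0,
    name: str | None = None,
    orientation: str = "sense",
    organism_mode: str = "human",
    read_len: int = 150,
    max_attempts: int = 50,
) -> ConstructSpec:
    """Random reporter construct with the study's structural features.

    The intron starts GT and ends AG and contains a centred branch-site
    interval (default 55 bp) recorded as an excluded interval; cut sites are
    ``sgA`` inside Exon1 and ``sgU``/``sgD`` at (or ``cut_offset_*`` nt
    outside) the intron boundaries.  ``branch_deleted`` excises the branch
    interval, shortening the intron by exactly ``branch_len``.

    Constructs are rejection-sampled (deterministically from ``seed``) until
    they are *diagnostic*: the flipped-segment probe region is absent from
    the intact and gap-repaired references, at least one microhomology pair
    is detectable within the read capture range for both cut configurations,
    and no spurious copy of the reference's last hexamer sits in the final
    12 nt of a truncated long read (which would wrongly trigger the 3'
    barcode check).
    """
    if min(exon1_len, intron_len, exon2_len) < 40:
        raise ConstructError("regions: exon/intron lengths must each be >= 40 nt")
    if intron_len <= branch_len + 10:
        raise ConstructError("regions: intron too short to host the branch site")
    if not (0 <= cut_offset_a < exon1_len - 30 and 0 <= cut_offset_b < exon2_len):
        raise ConstructError("cut_sites: cut offsets outside exons")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        exon1 = _random_dna(rng, exon1_len)
        intron = "GT" + _random_dna(rng, intron_len - 4) + "AG"
        exon2 = _random_dna(rng, exon2_len)
        b0 = exon1_len + (intron_len - branch_len) // 2
        seq = exon1 + intron + exon2
        total = len(seq)
        spec = ConstructSpec(
            name=name or f"synthetic-{seed}",
            sequence=seq,
            regions={
                "Exon1": (0, exon1_len),
                "Intron": (exon1_len, exon1_len + intron_len),
                "Exon2": (exon1_len + intron_len, total),
            },
            cut_sites={
                "sgA": max(30, exon1_len - 10),
                "sgU": exon1_len - cut_offset_a,
                "sgD": exon1_len + intron_len + cut_offset_b,
            },
            excluded_intervals={"branch_site": (b0, b0 + branch_len)},
            primer_span=(0, total),
            orientation=orientation,
            organism_mode=organism_mode,
        )
        if _construct_is_diagnostic(spec, read_len):
            break
    else:
        raise ConstructError(f"could not generate a diagnostic construct from seed {seed}")
    if branch_deleted:
        spec = with_branch_deleted(spec)
    return spec


def _construct_is_diagnostic(spec: ConstructSpec, read_len: int) -> bool:
    from .gap_repair import make_flip_probe

    amp = spec.amplicon
    ca = spec.to_amplicon_coord(spec.cut_sites["sgU"])
    cb = spec.to_amplicon_coord(spec.cut_sites["sgD"])
    ref2 = amp[:ca] + amp[cb:]
    try:
        make_flip_probe(spec, "sgU", "sgD")
    except ConstructError:
        return False
    capture = read_len - 6
    last6 = amp[-6:]
    for long_ref in (amp, derive_flipped_reference(spec, "sgU", "sgD")):
        trunc = long_ref[:capture]
        if len(long_ref) > capture and last6 in trunc[-12:]:
            return False
    for cu, cd in ((spec.cut_sites["sgA"],) * 2, (spec.cut_sites["sgU"], spec.cut_sites["sgD"])):
        if pick_mmej_pair_or_none(spec, cu, cd, capture=capture) is None:
            return False
    return True


def pick_mmej_pair_or_none(spec: ConstructSpec, cut_up: int, cut_down: int,
                           min_deletion: int = 0, capture: int = 144) -> MHPair | None:
    """Deterministically choose a detectable microhomology pair.

    The pair's deletion signature must lie fully within the read capture
    range of the repaired product and the deletion must span at least
    ``min_deletion`` nt.  Returns the eligible pair with the smallest such
    deletion (ties broken by genomic order).
    """
    cu = spec.to_amplicon_coord(cut_up)
    cd = spec.to_amplicon_coord(cut_down)
    pairs = enumerate_pairs(
        spec.amplicon, cu, cd,
        regions=spec.amplicon_regions(),
        excluded_intervals=spec.amplicon_excluded(),
    )
    eligible = [
        p for p in pairs
        if p.up_interval[0] >= 10 and p.up_interval[1] + 10 <= capture
        and p.deletion_size >= min_deletion
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda p: (p.deletion_size, p.up_interval[0]))


def pick_mmej_pair(spec: ConstructSpec, cut_up: int, cut_down: int,
                   min_deletion: int = 0, capture: int = 144) -> MHPair:
    p = pick_mmej_pair_or_none(spec, cut_up, cut_down, min_deletion, capture)
    if p is None:
        raise ValueError("no detectable microhomology pair for this cut configuration")
    return p


# -- read simulation -------------------------------------------------------

def _event_product(kind: str, spec: ConstructSpec, ca: int, cb: int | None,
                   pair_by_name: dict[str, MHPair], rng: np.random.Generator) -> tuple[str, str]:
    """Repair-product sequence (amplicon coordinates) and detail string."""
    amp = spec.amplicon
    if kind == "error_free":
        return amp, ""
    if kind.startswith("nhej_ins_seq:"):
        ins = kind.split(":", 1)[1]
        return amp[:ca] + ins + amp[ca:], ins
    if kind.startswith("nhej_ins:"):
        ins = _random_dna(rng, int(kind.split(":", 1)[1]))
        return amp[:ca] + ins + amp[ca:], ins
    if kind.startswith("nhej_del:"):
        d = int(kind.split(":", 1)[1])
        left = d // 2
        return amp[:ca - left] + amp[ca + (d - left):], str(d)
    if kind.startswith("mmej:"):
        pname = kind.split(":", 1)[1]
        pair = pair_by_name.get(pname)
        if pair is None:
            raise ValueError(f"unknown microhomology pair {pname!r}")
        s, e = pair.deletion_interval
        return amp[:s] + amp[e:], pname
    if kind == "popout" or kind.startswith("popout_"):
        if cb is None:
            raise ValueError("pop-out events need two cut sites")
        prod = amp[:ca] + amp[cb:]
        if kind.startswith("popout_ins:"):
            ins = _random_dna(rng, int(kind.split(":", 1)[1]))
            return prod[:ca] + ins + prod[ca:], ins
        if kind.startswith("popout_del:"):
            d = int(kind.split(":", 1)[1])
            left = d // 2
            return prod[:ca - left] + prod[ca + (d - left):], str(d)
        return prod, ""
    if kind == "flipped":
        if cb is None:
            raise ValueError("flipped events need two cut sites")
        return derive_flipped_reference(spec, _cut_name(spec, ca), _cut_name(spec, cb)), ""
    if kind == "rtdr":
        i0, i1 = spec.amplicon_regions()["Intron"]
        return amp[:i0] + amp[i1:], ""
    if kind == "noise":
        return amp[:6] + _random_dna(rng, len(amp) - 6), ""
    raise ValueError(f"unknown event kind {kind!r}")


def _cut_name(spec: ConstructSpec, amp_coord: int) -> str:
    for gname, c in spec.cut_sites.items():
        if spec.to_amplicon_coord(c) == amp_coord:
            return gname
    raise ValueError(f"no cut site at amplicon coordinate {amp_coord}")


def default_scheme(spec: ConstructSpec, code: str = "ACGT") -> BarcodeScheme:
    amp = spec.amplicon
    return BarcodeScheme(code=code, ref_first6=amp[:6], ref_last6=amp[-6:])


def simulate_reads(
    construct: ConstructSpec,
    mix: EventMix,
    n: int,
    barcode: str = "ACGT",
    read_len: int = 150,
    cut_a: str = "sgA",
    cut_b: str | None = None,
    paired: bool = False,
    id_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Simulate a barcoded amplicon library.

    Returns FASTQ-ready ``(read_id, sequence, quality)`` records (two per
    fragment in paired mode, the mate reverse-complemented and suffixed
    ``/2``) and one truth record per fragment.
    """
    rng = np.random.default_rng(mix.seed)
    ca = construct.to_amplicon_coord(construct.cut_sites[cut_a])
    cb = construct.to_amplicon_coord(construct.cut_sites[cut_b]) if cut_b else None
    pairs = enumerate_pairs(
        construct.amplicon, ca, cb if cb is not None else ca,
        regions=construct.amplicon_regions(),
        excluded_intervals=construct.amplicon_excluded(),
    )
    pair_by_name = {p.name: p for p in pairs}
    kinds = sorted(mix.fractions)
    cdf = np.cumsum([mix.fractions[k] for k in kinds])
    draws = rng.random(n)
    records: list[tuple[str, str, str]] = []
    truths: list[TruthRecord] = []
    for i in range(n):
        kind = kinds[int(np.searchsorted(cdf, draws[i], side="right"))] if draws[i] < cdf[-1] else kinds[-1]
        product, detail = _event_product(kind, construct, ca, cb, pair_by_name, rng)
        nn5 = _random_dna(rng, 2)
        nn3 = _random_dna(rng, 2)
        fragment = nn5 + barcode + product + barcode + nn3
        read = fragment[:read_len]
        read = _apply_substitutions(read, mix.sub_error_rate, rng)
        rid = f"{id_prefix}{i:06d}"
        records.append((rid, read, "I" * len(read)))
        if paired:
            mate = _revcomp(fragment)[:read_len]
            mate = _apply_substitutions(mate, mix.sub_error_rate, rng)
            records.append((f"{rid}/2", mate, "I" * len(mate)))
        truths.append(TruthRecord(rid, kind, detail))
    return records, truths


def _revcomp(seq: str) -> str:
    from .reference_model import revcomp
    return revcomp(seq)


def _apply_substitutions(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not read:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return read
    for h in hits:
        choices = BASES[BASES != arr[h]]
        arr[h] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode()


# -- FASTQ / truth-table IO ------------------------------------------------

def write_fastq(records: list[tuple[str, str, str]], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            out.append((header[1:].rstrip("\n").split()[0], seq, qual))
    return out


def write_truth(truths: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_event\tdetails\n")
        for t in truths:
            fh.write(f"{t.read_id}\t{t.true_event}\t{t.details}\n")
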
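"""Construct definitions and derived repair references.

A *construct* is the amplicon-bearing reporter: a DNA sequence annotated with
three ordered regions (Exon1, Intron, Exon2), one or more Cas9 cut sites,
optional excluded intervals (e.g. the branch site, which is absent from the
non-splicing deletion construct), and the span covered by the sequencing
primers.  Every classifier downstream works on sequences derived here:

* the intact amplicon (``ref_1dsb``) — the construct restricted to the primer
  span, used for single-cut libraries and intron-retention products;
* the gap-repaired amplicon (``ref_2dsb``) — the intact amplicon with the
  segment between the two cuts removed, used for double-cut libraries;
* the flipped amplicon (``ref_flipped``) — the intact amplicon with the
  inter-cut segment replaced by its reverse complement.

Coordinates are 0-based, half-open throughout.  A cut site is an integer
``c`` meaning a blunt cut between positions ``c-1`` and ``c``; relative
position ``+k`` maps to ``ref[c+k-1]`` and ``-k`` to ``ref[c-k]`` (there is
no position 0), so a +/-10 window holds exactly 20 reference nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_NAMES = ("Exon1", "Intron", "Exon2")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ConstructError(ValueError):
    """Raised when a construct definition violates its invariants."""


@dataclass(frozen=True)
class ConstructSpec:
    """A validated reporter construct.

    ``regions``, ``cut_sites`` and ``excluded_intervals`` use construct
    coordinates; ``primer_span`` delimits the sequenced amplicon.
    """

    name: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    cut_sites: dict[str, int]
    excluded_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    primer_span: tuple[int, int] = (0, 0)
    orientation: str = "sense"
    organism_mode: str = "human"

    def __post_init__(self):
        if self.primer_span == (0, 0):
            object.__setattr__(self, "primer_span", (0, len(self.sequence)))
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - set("ACGT"):
            raise ConstructError(f"sequence: non-ACGT characters in construct {self.name!r}")
        ps, pe = self.primer_span
        if not (0 <= ps < pe <= len(seq)):
            raise ConstructError("primer_span: outside sequence")
        missing = [r for r in REGION_NAMES if r not in self.regions]
        if missing:
            raise ConstructError(f"regions: missing {missing}")
        prev_end = None
        prev_name = None
        for rname in REGION_NAMES:
            s, e = self.regions[rname]
            if not (ps <= s < e <= pe):
                raise ConstructError(f"regions: {rname} outside primer_span")
            if prev_end is not None and s < prev_end:
                raise ConstructError(f"regions: {rname} overlaps {prev_name}")
            prev_end, prev_name = e, rname
        for gname, c in self.cut_sites.items():
            if not (ps < c < pe):
                raise ConstructError(f"cut_sites: {gname} cut at {c} not strictly inside primer_span")
        for ename, (s, e) in self.excluded_intervals.items():
            if not (0 <= s < e <= len(seq)):
                raise ConstructError(f"excluded_intervals: {ename} outside sequence")
        if self.orientation not in ("sense", "antisense"):
            raise ConstructError("orientation: must be 'sense' or 'antisense'")
        if self.organism_mode not in ("human", "yeast"):
            raise ConstructError("organism_mode: must be 'human' or 'yeast'")

    # -- accessors --------------------------------------------------------
    @property
    def amplicon(self) -> str:
        """Sequence between the sequencing primers (the intact reference)."""
        ps, pe = self.primer_span
        return self.sequence[ps:pe]

    def region_at(self, pos: int) -> str | None:
        """Region name containing construct position ``pos`` (None outside)."""
        for rname in REGION_NAMES:
            s, e = self.regions[rname]
            if s <= pos < e:
                return rname
        return None

    def to_amplicon_coord(self, pos: int) -> int:
        return pos - self.primer_span[0]

    def amplicon_regions(self) -> dict[str, tuple[int, int]]:
        """Regions re-expressed in amplicon (primer-span) coordinates, clipped."""
        ps, pe = self.primer_span
        out = {}
        for rname in REGION_NAMES:
            s, e = self.regions[rname]
            s, e = max(s, ps) - ps, min(e, pe) - ps
            if s < e:
                out[rname] = (s, e)
        return out

    def amplicon_excluded(self) -> dict[str, tuple[int, int]]:
        ps, pe = self.primer_span
        out = {}
        for ename, (s, e) in self.excluded_intervals.items():
            s, e = max(s, ps) - ps, min(e, pe) - ps
            if s < e:
                out[ename] = (s, e)
        return out


@dataclass(frozen=True)
class ReferenceSet:
    """References for one (pair of) cut site(s) on a construct.

    ``cut_in_ref1`` is the upstream cut in intact-amplicon coordinates;
    ``cut_in_ref2`` is the fused junction in gap-repaired coordinates
    (identical by construction since the prefix is shared).
    """

    ref_1dsb: str
    ref_2dsb: str
    ref_flipped: str
    cut_in_ref1: int
    cut_in_ref2: int
    gap_span: int

    def __post_init__(self):
        assert len(self.ref_2dsb) == len(self.ref_1dsb) - self.gap_span
        assert len(self.ref_flipped) == len(self.ref_1dsb)


def derive_references(construct: ConstructSpec, cut_a: str, cut_b: str | None = None) -> ReferenceSet:
    """Build the intact / gap-repaired / flipped references for given cuts.

    With a single cut the gap-repaired and flipped references degenerate to
    the intact amplicon (gap span 0).
    """
    ref1 = construct.amplicon
    ca = construct.to_amplicon_coord(_cut(construct, cut_a))
    if cut_b is None:
        return ReferenceSet(ref1, ref1, ref1, ca, ca, 0)
    cb = construct.to_amplicon_coord(_cut(construct, cut_b))
    if cb <= ca:
        raise ConstructError(f"cut_sites: {cut_b} ({cb}) must lie strictly downstream of {cut_a} ({ca})")
    ref2 = ref1[:ca] + ref1[cb:]
    flipped = derive_flipped_reference(construct, cut_a, cut_b)
    return ReferenceSet(ref1, ref2, flipped, ca, ca, cb - ca)


def derive_flipped_reference(construct: ConstructSpec, cut_a: str, cut_b: str) -> str:
    """Intact amplicon with the inter-cut segment reverse-complemented.

    Models re-insertion of the excised segment in the opposite orientation;
    applying the operation twice returns the intact amplicon.
    """
    ref1 = construct.amplicon
    ca = construct.to_amplicon_coord(_cut(construct, cut_a))
    cb = construct.to_amplicon_coord(_cut(construct, cut_b))
    if cb <= ca:
        raise ConstructError(f"cut_sites: {cut_b} ({cb}) must lie strictly downstream of {cut_a} ({ca})")
    return ref1[:ca] + revcomp(ref1[ca:cb]) + ref1[cb:]


def _cut(construct: ConstructSpec, name: str) -> int:
    try:
        return construct.cut_sites[name]
    except KeyError:
        raise ConstructError(f"cut_sites: unknown sgRNA {name!r}") from None


# -- serialisation ---------------------------------------------------------
#
# On disk a construct is a FASTA record plus a BED-like TSV of intervals
# (name, start, end, kind with kind in {region, excluded, primer_span}) and a
# YAML stanza holding cut sites and scalar metadata.  All 0-based half-open.

def write_construct(spec: ConstructSpec, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{spec.name}.fasta"
    tsv = outdir / f"{spec.name}.regions.tsv"
    yml = outdir / f"{spec.name}.yaml"
    SeqIO.write([SeqRecord(Seq(spec.sequence), id=spec.name, description="")], str(fasta), "fasta")
    with open(tsv, "w") as fh:
        fh.write("name\tstart\tend\tkind\n")
        for rname in REGION_NAMES:
            s, e = spec.regions[rname]
            fh.write(f"{rname}\t{s}\t{e}\tregion\n")
        for ename, (s, e) in spec.excluded_intervals.items():
            fh.write(f"{ename}\t{s}\t{e}\texcluded\n")
        ps, pe = spec.primer_span
        fh.write(f"primer_span\t{ps}\t{pe}\tprimer_span\n")
    with open(yml, "w") as fh:
        yaml.safe_dump(
            {
                "name": spec.name,
                "cut_sites": dict(spec.cut_sites),
                "orientation": spec.orientation,
                "organism_mode": spec.organism_mode,
            },
            fh,
        )
    return {"fasta": fasta, "annotation": tsv, "meta": yml}


def load_construct(fasta: str | Path, annotation: str | Path | dict) -> ConstructSpec:
    """Load and validate a construct from FASTA + annotation.

    ``annotation`` is either the path of the interval TSV (the YAML stanza is
    looked up next to it, ``<name>.yaml`` for ``<name>.regions.tsv``) or an
    in-memory record with keys ``regions``, ``cut_sites``, ``primer_span``
    and optionally ``excluded_intervals``/``orientation``/``organism_mode``.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ConstructError(f"sequence: FASTA must contain exactly one record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if isinstance(annotation, dict):
        rec = annotation
        return ConstructSpec(
            name=rec.get("name", records[0].id),
            sequence=seq,
            regions={k: tuple(v) for k, v in rec["regions"].items()},
            cut_sites=dict(rec["cut_sites"]),
            excluded_intervals={k: tuple(v) for k, v in rec.get("excluded_intervals", {}).items()},
            primer_span=tuple(rec.get("primer_span", (0, len(seq)))),
            orientation=rec.get("orientation", "sense"),
            organism_mode=rec.get("organism_mode", "human"),
        )
    annotation = Path(annotation)
    regions: dict[str, tuple[int, int]] = {}
    excluded: dict[str, tuple[int, int]] = {}
    primer_span = (0, len(seq))
    with open(annotation) as fh:
        header = fh.readline()
        if header.strip() != "name\tstart\tend\tkind":
            raise ConstructError("annotation: unexpected TSV header")
        for line in fh:
            name, s, e, kind = line.rstrip("\n").split("\t")
            iv = (int(s), int(e))
            if kind == "region":
                regions[name] = iv
            elif kind == "excluded":
                excluded[name] = iv
            elif kind == "primer_span":
                primer_span = iv
            else:
                raise ConstructError(f"annotation: unknown interval kind {kind!r}")
    stem = annotation.name
    if stem.endswith(".regions.tsv"):
        stem = stem[: -len(".regions.tsv")]
    yml = annotation.with_name(stem + ".yaml")
    with open(yml) as fh:
        meta = yaml.safe_load(fh)
    return ConstructSpec(
        name=meta.get("name", records[0].id),
        sequence=seq,
        regions=regions,
        cut_sites={k: int(v) for k, v in meta["cut_sites"].items()},
        excluded_intervals=excluded,
        primer_span=primer_span,
        orientation=meta.get("orientation", "sense"),
        organism_mode=meta.get("organism_mode", "human"),
    )


def with_branch_deleted(spec: ConstructSpec, branch_name: str = "branch_site", suffix: str = "-branchdel") -> ConstructSpec:
    """Return the construct with its branch interval excised.

    All coordinates downstream of the deletion shift left; the excluded
    interval itself is dropped (it no longer exists in this construct).
    """
    if branch_name not in spec.excluded_intervals:
        raise ConstructError(f"excluded_intervals: no interval named {branch_name!r}")
    bs, be = spec.excluded_intervals[branch_name]
    blen = be - bs

    def shift(p: int) -> int:
        if p <= bs:
            return p
        if p >= be:
            return p - blen
        raise ConstructError(f"cannot delete {branch_name}: a feature boundary lies inside it")

    return replace(
        spec,
        name=spec.name + suffix,
        sequence=spec.sequence[:bs] + spec.sequence[be:],
        regions={k: (shift(s), shift(e)) for k, (s, e) in spec.regions.items()},
        cut_sites={k: shift(c) for k, c in spec.cut_sites.items()},
        excluded_intervals={k: (shift(s), shift(e)) for k, (s, e) in spec.excluded_intervals.items() if k != branch_name},
        primer_span=(shift(spec.primer_span[0]), shift(spec.primer_span[1])),
    )
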
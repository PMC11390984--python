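"""End-to-end orchestration: trim -> barcode -> classify -> report.

`LibraryContext` bundles everything derived from a construct and a cut
selection (references, microhomology catalog, deletion signatures, barcode
scheme) so the per-read classifiers can be applied uniformly.  The pipeline
runs from a YAML configuration, writes per-read and summary TSVs plus the
pair catalog, window tables and graphs, and logs per-stage read counts (the
stage-survival accounting).  Given identical inputs and seed the outputs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .end_joining import Alignment, align_to_reference, classify_library_1dsb, realign_encapsulate
from .gap_repair import classify_library_2dsb, make_flip_probe
from .microhomology import build_signature, enumerate_pairs, pair_catalog_rows
from .read_prep import BarcodeScheme, prepare_library
from .reference_model import ConstructSpec, ReferenceSet, derive_references, load_construct
from .stats import frequency_report
from .variation_graphs import build_graph, extract_window, position_histogram, window_table


@dataclass
class LibraryContext:
    construct: ConstructSpec
    refs: ReferenceSet
    cut_a: str
    cut_b: str | None
    pairs: list
    signatures: list
    flip_probe: str | None = None

    @property
    def reference(self) -> str:
        """Classification reference: gap-repaired for two cuts, intact else."""
        return self.refs.ref_2dsb if self.cut_b else self.refs.ref_1dsb

    @property
    def cut(self) -> int:
        return self.refs.cut_in_ref2 if self.cut_b else self.refs.cut_in_ref1

    def scheme(self, code: str) -> BarcodeScheme:
        amp = self.refs.ref_1dsb
        return BarcodeScheme(code=code, ref_first6=amp[:6], ref_last6=amp[-6:])


def make_context(construct: ConstructSpec, cut_a: str, cut_b: str | None = None,
                 with_flip_probe: bool = False) -> LibraryContext:
    refs = derive_references(construct, cut_a, cut_b)
    cu = refs.cut_in_ref1
    cd = cu + refs.gap_span
    pairs = enumerate_pairs(
        refs.ref_1dsb, cu, cd,
        regions=construct.amplicon_regions(),
        excluded_intervals=construct.amplicon_excluded(),
    )
    # a signature that also occurs in the intact amplicon cannot distinguish
    # an MMEJ product from an uncut molecule (this arises when flank
    # truncation at the primer boundary degenerates the junction context);
    # such pairs stay in the catalog but are excluded from detection
    signatures = [
        sig for sig in (build_signature(p, refs.ref_1dsb) for p in pairs)
        if sig.sequence not in refs.ref_1dsb
    ]
    probe = make_flip_probe(construct, cut_a, cut_b) if (with_flip_probe and cut_b) else None
    return LibraryContext(construct, refs, cut_a, cut_b, pairs, signatures, probe)


# -- SAM ingestion ---------------------------------------------------------

def alignments_from_sam(path: str | Path, reference: str) -> list[Alignment | None]:
    """Convert externally produced SAM records to pipeline alignments.

    Unmapped records and records not anchored at reference position 0 give
    ``None`` (the caller counts them as rejected).  Mismatches are recovered
    by comparing the query to the reference.
    """
    import pysam

    out: list[Alignment | None] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_start != 0 or rec.query_sequence is None:
                out.append(None)
                continue
            read = rec.query_sequence
            ops = []
            r = q = 0
            for op, ln in rec.cigartuples or []:
                if op in (0, 7, 8):  # M/=/X: split by actual identity
                    for k in range(ln):
                        kind = "M" if read[q + k] == reference[r + k] else "X"
                        if ops and ops[-1][0] == kind and ops[-1][1] + ops[-1][2] == r + k:
                            ops[-1] = (kind, ops[-1][1], ops[-1][2] + 1)
                        else:
                            ops.append((kind, r + k, 1))
                    r += ln
                    q += ln
                elif op == 1:  # I
                    ops.append(("I", r, read[q:q + ln]))
                    q += ln
                elif op in (2, 3):  # D/N
                    ops.append(("D", r, ln))
                    r += ln
                elif op == 4:  # soft clip
                    q += ln
            out.append(Alignment(rec.query_name, read, ops))
    return out


# -- configuration ---------------------------------------------------------

@dataclass
class RunConfig:
    mode: str                       # 1dsb | 2dsb | 2dsb_exonic | yeast_2dsb | rnaseq
    construct_fasta: str
    construct_annotation: str
    cut_a: str
    cut_b: str | None
    libraries: list[dict]           # fastq, barcode, repeat, label
    outdir: str
    min_len: int = 130
    length_threshold: int = 130
    window_half: int = 10
    anchor: int = 20
    min_freq: float = 1e-5
    probe_k: int = 20
    probe_offset: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("1dsb", "2dsb", "2dsb_exonic", "yeast_2dsb", "rnaseq"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "1dsb" and self.cut_b is None:
            raise ValueError(f"mode {self.mode} requires two cut sites")
        for f in ("min_len", "length_threshold", "window_half", "anchor", "probe_k"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not self.libraries:
            raise ValueError("no libraries configured")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-mode analysis; returns the report bundle paths.

    Fails before writing anything if the configuration or any input is
    invalid or any FASTQ is empty.
    """
    from .synthetic_data import read_fastq

    config.validate()
    construct = load_construct(config.construct_fasta, config.construct_annotation)
    ctx = make_context(construct, config.cut_a, config.cut_b,
                       with_flip_probe=config.mode in ("2dsb", "2dsb_exonic"))
    libraries = []
    for lib in config.libraries:
        records = read_fastq(lib["fastq"])
        if not records:
            raise ValueError(f"empty FASTQ: {lib['fastq']}")
        libraries.append((lib, records))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "config_hash": _config_hash(config), "stages": []}
    bundle: dict = {"outdir": str(outdir)}

    pd.DataFrame(pair_catalog_rows(ctx.pairs, ctx.refs.ref_1dsb)).to_csv(
        outdir / "pair_catalog.tsv", sep="\t", index=False)
    bundle["pair_catalog"] = str(outdir / "pair_catalog.tsv")

    summaries = []
    windows_per_repeat, totals = [], []
    for lib, records in libraries:
        label = lib.get("label", Path(lib["fastq"]).stem)
        scheme = ctx.scheme(lib["barcode"])
        accepted, tally = prepare_library(records, scheme, strand=lib.get("strand", "forward"))
        log["stages"].append({"library": label, "stage": "barcode", "in": len(records), "out": len(accepted)})
        if config.mode == "1dsb":
            calls, freqs = classify_library_1dsb(
                accepted, ctx.reference, ctx.cut, ctx.signatures, min_len=config.min_len)
            rows = [{"read_id": c.read_id, "category": c.category,
                     "details": ";".join(sorted(c.pairs))} for c in calls]
            wins = []
            for c in calls:
                if c.category in ("error_free_uncut", "nhej_indel") and c.aln is not None:
                    w = extract_window(c.aln, ctx.reference, ctx.cut,
                                       half=config.window_half, anchor=config.anchor)
                    if not isinstance(w, str):
                        wins.append(w)
            windows_per_repeat.append(wins)
            totals.append(len(accepted))
        else:
            calls, freqs = classify_library_2dsb(
                accepted, ctx.signatures, flip_probe=ctx.flip_probe,
                length_threshold=config.length_threshold)
            rows = [{"read_id": c.read_id, "category": c.category,
                     "details": ";".join(sorted(c.pairs)), "flipped": int(c.flipped)}
                    for c in calls]
        per_read = outdir / f"{label}.per_read.tsv"
        pd.DataFrame(rows).to_csv(per_read, sep="\t", index=False)
        log["stages"].append({"library": label, "stage": "classify",
                              "in": len(accepted), "out": len(rows)})
        summaries.append(freqs)

    report = frequency_report(summaries)
    report.to_csv(outdir / "summary.tsv", sep="\t")
    bundle["summary"] = str(outdir / "summary.tsv")

    if config.mode == "1dsb" and windows_per_repeat and any(totals):
        table = window_table(windows_per_repeat, totals)
        table.reset_index().to_csv(outdir / "window_table.tsv", sep="\t", index=False)
        g = build_graph(table, min_freq=config.min_freq)
        import networkx as nx
        nx.write_graphml(g, outdir / "variation_graph.graphml")
        position_histogram(table, half=config.window_half).to_csv(
            outdir / "position_histogram.tsv", sep="\t")
        bundle["window_table"] = str(outdir / "window_table.tsv")
        bundle["variation_graph"] = str(outdir / "variation_graph.graphml")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    bundle["log"] = str(outdir / "run_log.json")
    return bundle
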
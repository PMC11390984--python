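#!/usr/bin/env python
"""Simulate the barcoded amplicon libraries used by the downstream steps.

Four biological replicates per condition: single-cut (1-DSB) libraries for
the splicing and non-splicing constructs in two simulated cell types (with a
planted two-fold MMEJ contrast in the splicing construct), one double-cut
(2-DSB) library with pop-out / flip / MMEJ events, and one yeast-mode
library carrying an RNA-identical repair fraction.  FASTQ and truth tables
go to scratch/sim/ (they are large and regenerable); the library manifest
goes to results/.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

build_all = import_module("01_build_constructs").build_all  # noqa: E402

from dsbrepair.synthetic_data import (  # noqa: E402
    EventMix,
    pick_mmej_pair,
    simulate_reads,
    write_fastq,
    write_truth,
)

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")
N_READS = 4_000
ERROR_RATE = 0.005


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    specs = build_all(args.seed)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    manifest = []

    def emit(label, spec, mix, cut_a, cut_b, meta):
        records, truths = simulate_reads(spec, mix, N_READS, cut_a=cut_a, cut_b=cut_b)
        fq = SCRATCH / f"{label}.fastq"
        write_fastq(records, fq)
        write_truth(truths, SCRATCH / f"{label}.truth.tsv")
        manifest.append({"label": label, "fastq": str(fq), "n_reads": N_READS,
                         "construct": spec.name, **meta})

    # 1-DSB: 2 cell types x {sense, branchdel} x 4 replicates
    for cname, spec in (("sense", specs["sense"]), ("branchdel", specs["sense-branchdel"])):
        pair = pick_mmej_pair(spec, spec.cut_sites["sgA"], spec.cut_sites["sgA"],
                              min_deletion=100 if cname == "sense" else 40)
        for cell in (1, 2):
            mmej = 0.16 if (cell == 1 and cname == "sense") else 0.08
            for rep in range(1, 5):
                mix = EventMix(
                    {"error_free": 0.78 - mmej, "nhej_ins:1": 0.06, "nhej_ins:2": 0.04,
                     "nhej_del:1": 0.05, "nhej_del:2": 0.03, "nhej_del:3": 0.02,
                     f"mmej:{pair.name}": mmej, "noise": 0.02},
                    sub_error_rate=ERROR_RATE,
                    seed=args.seed * 10_000 + cell * 1000 + (cname == "sense") * 100 + rep)
                emit(f"1dsb_{cname}_cell{cell}_rep{rep}", spec, mix, "sgA", None,
                     {"mode": "1dsb", "cell_type": cell, "replicate": rep,
                      "planted_mmej": mmej, "mmej_pair": pair.name})

    # 2-DSB: sense construct, 4 replicates
    spec = specs["sense"]
    pair2 = pick_mmej_pair(spec, spec.cut_sites["sgU"], spec.cut_sites["sgD"])
    for rep in range(1, 5):
        mix = EventMix(
            {"error_free": 0.40, "popout": 0.20, "popout_ins:2": 0.05, "popout_del:3": 0.05,
             f"mmej:{pair2.name}": 0.20, "flipped": 0.10},
            sub_error_rate=ERROR_RATE, seed=args.seed * 10_000 + 5000 + rep)
        emit(f"2dsb_sense_rep{rep}", spec, mix, "sgU", "sgD",
             {"mode": "2dsb", "replicate": rep, "mmej_pair": pair2.name})

    # yeast mode with an R-TDR fraction
    for rep in range(1, 5):
        mix = EventMix({"error_free": 0.55, "popout": 0.42, "rtdr": 0.03},
                       sub_error_rate=0.0, seed=args.seed * 10_000 + 6000 + rep)
        emit(f"yeast_rep{rep}", specs["yeast"], mix, "sgU", "sgD",
             {"mode": "yeast_2dsb", "replicate": rep, "planted_rtdr": 0.03})

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(manifest).to_csv(RESULTS / "library_manifest.tsv", sep="\t", index=False)
    print(f"Simulated {len(manifest)} libraries of {N_READS} reads each "
          f"(substitution error {ERROR_RATE}) under {SCRATCH}/")
    print(f"Manifest: {RESULTS / 'library_manifest.tsv'}")


if __name__ == "__main__":
    main()
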
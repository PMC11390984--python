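#!/usr/bin/env python
"""DSB-sequence windows, the variation-distance graph and the
variation-position histogram for the single-cut libraries.

Windows (+/-10 nt around the cut, anchor-filtered, substitutions masked)
are aggregated over the four replicates of each construct/cell-type; the
graph connects windows one single-nucleotide in/del apart, and a
sense-vs-branch-deletion comparison graph colours vertices by the log
frequency ratio.
"""

import argparse
import sys
from importlib import import_module
from pathlib import Path

import networkx as nx
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
build_all = import_module("01_build_constructs").build_all  # noqa: E402

from dsbrepair.end_joining import classify_library_1dsb  # noqa: E402
from dsbrepair.pipeline import make_context  # noqa: E402
from dsbrepair.read_prep import prepare_library  # noqa: E402
from dsbrepair.synthetic_data import default_scheme, read_fastq  # noqa: E402
from dsbrepair.variation_graphs import (  # noqa: E402
    build_graph,
    comparison_graph,
    extract_window,
    plot_graph,
    position_histogram,
    window_table,
)

RESULTS = Path("results")


def windows_for(spec, ctx, libs):
    per_rep, totals = [], []
    for _, lib in libs.iterrows():
        records = read_fastq(lib["fastq"])
        accepted, _ = prepare_library(records, default_scheme(spec))
        calls, _ = classify_library_1dsb(accepted, ctx.reference, ctx.cut, ctx.signatures)
        wins = []
        for c in calls:
            if c.category in ("error_free_uncut", "nhej_indel") and c.aln is not None:
                w = extract_window(c.aln, ctx.reference, ctx.cut)
                if not isinstance(w, str):
                    wins.append(w)
        per_rep.append(wins)
        totals.append(len(accepted))
    return window_table(per_rep, totals)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--min-freq", type=float, default=1e-5)
    args = parser.parse_args()
    specs = build_all(args.seed)
    manifest = pd.read_csv(RESULTS / "library_manifest.tsv", sep="\t")
    m1 = manifest[(manifest["mode"] == "1dsb") & (manifest["cell_type"] == 1)]

    tables = {}
    for label in ("sense", "sense-branchdel"):
        spec = specs[label]
        ctx = make_context(spec, "sgA")
        table = windows_for(spec, ctx, m1[m1["construct"] == label])
        tables[label] = table
        table.reset_index().to_csv(RESULTS / f"window_table_{label}.tsv", sep="\t", index=False)
        g = build_graph(table, min_freq=args.min_freq)
        nx.write_graphml(g, RESULTS / f"variation_graph_{label}.graphml")
        plot_graph(g, RESULTS / f"variation_graph_{label}.svg", title=label)
        position_histogram(table).to_csv(RESULTS / f"position_histogram_{label}.tsv", sep="\t")
        print(f"{label}: {len(table)} distinct windows, graph has "
              f"{g.number_of_nodes()} vertices / {g.number_of_edges()} edges")

    cg = comparison_graph(tables["sense"], tables["sense-branchdel"], min_freq=args.min_freq)
    nx.write_graphml(cg, RESULTS / "comparison_graph.graphml")
    plot_graph(cg, RESULTS / "comparison_graph.svg", title="sense vs branch-deletion")
    print(f"comparison graph: {cg.number_of_nodes()} vertices / {cg.number_of_edges()} edges")


if __name__ == "__main__":
    main()
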
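#!/usr/bin/env python
"""Optional validation against real-genome numbers (requires external data).

Given a locally downloaded genome FASTA and the tabular output of a tRNA
gene predictor run on it (nuclear chromosomes), recomputes:

  t2  number of nuclear tRNA genes
  t3  number of distinct isodecoder clusters (identical mature sequences)
  t4  number of distinct anticodons
  t5  number of sense anticodons absent from the repertoire
  t6  missing anticodons compensated via G:U or I:C arcs of the
      decoding-potential graph

Usage:
    python scripts/validate_external.py --genome genome.fasta \
        --trnascan trnascan_output.tsv --out results.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from trnakit.fasta import read_fasta
from trnakit.genetic_code import STANDARD_CODE
from trnakit.repertoire import cluster_isodecoders, parse_trnascan
from trnakit.wobble_graph import build_graph, compensated_missing


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genome", type=Path, required=True)
    parser.add_argument("--trnascan", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    genes = parse_trnascan(args.trnascan)
    genome = read_fasta(args.genome)
    clusters = cluster_isodecoders(genes, genome)
    anticodons = {g.anticodon for g in genes if g.has_anticodon}
    # graph vertices exclude the TGA-suppressor anticodon (selenocysteine)
    existing = anticodons & STANDARD_CODE.sense_anticodons
    graph = build_graph(STANDARD_CODE, existing)
    results = {
        "t2": {"value": len(genes), "n": len(genes)},
        "t3": {"value": len(clusters), "n": len(genes)},
        "t4": {"value": len(anticodons), "n": len(genes)},
        "t5": {"value": len(graph.missing), "n": len(graph.vertices)},
        "t6": {
            "value": len(compensated_missing(graph, {"G:U", "I:C"})),
            "n": len(graph.missing),
        },
    }
    text = json.dumps(results, indent=2)
    if args.out:
        args.out.write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
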
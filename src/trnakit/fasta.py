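"""Thin FASTA helpers used across stages.

Reading is delegated to Biopython; sequences are returned as plain upper-case
strings keyed by record id, which is the representation the coordinate
arithmetic in this package operates on.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping

from Bio import SeqIO


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict:
    """Load a (possibly gzipped) FASTA file into {id: sequence}."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
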
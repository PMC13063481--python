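"""Genomic codon usage from CDS and the multi-level correlation report."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import AA_1TO3, GeneticCode, STANDARD_CODE, anticodon_of, codon_of
from .wobble_graph import (
    DecodingPotentialGraph,
    CorrelationResult,
    group_by_arcs,
    pearson_with_p,
    WOBBLE_RULES,
)

_ACGT = frozenset("ACGT")


@dataclass
class CodonUsage:
    """Pooled codon counts over all CDS records.

    Stop codons are never counted (TGA is a stop under the default
    selenocysteine-exclusion policy); triplets containing non-ACGT characters
    are tallied in ``n_ambiguous``.
    """

    counts: dict
    n_cds: int = 0
    n_stop: int = 0
    n_ambiguous: int = 0
    n_incomplete: int = 0  # records whose length is not divisible by 3
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    @property
    def aa_counts(self) -> dict:
        """Push-forward of codon counts through the genetic code."""
        out: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = self.code.aa(codon)
            out[aa] = out.get(aa, 0) + n
        return out

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        total = self.total or 1
        rows = [
            (c, self.code.aa(c), AA_1TO3[self.code.aa(c)], n, 1000.0 * n / total)
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["codon", "aa", "isotype", "count", "per_mille"])


def count_codons(cds, code: GeneticCode = STANDARD_CODE) -> CodonUsage:
    """Count in-frame codons over a CDS FASTA path or an iterable of
    (id, sequence) pairs.

    Every record is read from position 1 in non-overlapping triplets; a
    trailing partial triplet flags the record as incomplete and is dropped.
    """
    if isinstance(cds, (str, Path)):
        from .fasta import read_fasta

        cds = read_fasta(cds).items()
    usage = CodonUsage(counts={c: 0 for c in sorted(code.sense_codons)}, code=code)
    for _rec_id, seq in cds:
        seq = str(seq).upper()
        usage.n_cds += 1
        if len(seq) % 3:
            usage.n_incomplete += 1
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if not set(codon) <= _ACGT:
                usage.n_ambiguous += 1
            elif code.is_stop(codon):
                usage.n_stop += 1
            else:
                usage.counts[codon] += 1
    if usage.n_cds == 0:
        warnings.warn("empty CDS stream: zero codon usage", stacklevel=2)
    return usage


CORRELATION_LEVELS = ("isotype", "isoacceptor", "graph_grouped", "per_wobble_type")


def _level_vectors(
    usage: CodonUsage, copy_number: Mapping[str, float], code: GeneticCode
):
    """(x, y) per level: isotype pairs amino-acid usage with summed copies;
    isoacceptor pairs each sense codon's usage with its exact-anticodon copies
    (0 for missing)."""
    aa_usage = usage.aa_counts
    aa_copies: dict[str, float] = {aa: 0.0 for aa in sorted(set(code.table.values()))}
    for codon in code.sense_codons:
        aa_copies[code.aa(codon)] += copy_number.get(anticodon_of(codon), 0)
    aas = sorted(aa_copies)
    isotype = (
        [aa_copies[a] for a in aas],
        [aa_usage.get(a, 0) for a in aas],
    )
    codons = sorted(code.sense_codons)
    isoacceptor = (
        [copy_number.get(anticodon_of(c), 0) for c in codons],
        [usage.counts.get(c, 0) for c in codons],
    )
    return isotype, isoacceptor


def correlate_levels(
    usage: CodonUsage,
    copy_number: Mapping[str, float],
    graph: DecodingPotentialGraph,
    graph_mode: str = "per_arc",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of copy numbers vs usage at every level.

    Levels: isotype (amino-acid marginals), isoacceptor (exact cognate
    anticodon per sense codon, missing = 0), graph_grouped (rows of
    :func:`group_by_arcs` under ``graph_mode``) and per_wobble_type (per-arc
    rows restricted to one wobble label).  Returns a tidy frame with columns
    level, mode, r, p, n.
    """
    code = graph.code
    isotype, isoacceptor = _level_vectors(usage, copy_number, code)
    rows = []

    def add(level, mode, x, y):
        res = pearson_with_p(x, y, log_transform=log_transform)
        rows.append((level, mode, res.r, res.p, res.n, res.degenerate))

    add("isotype", "", *isotype)
    add("isoacceptor", "", *isoacceptor)
    grouped = group_by_arcs(graph, copy_number, usage.counts, mode=graph_mode)
    add("graph_grouped", graph_mode, grouped["copies"], grouped["usage"])
    per_arc = group_by_arcs(graph, copy_number, usage.counts, mode="per_arc")
    for label in WOBBLE_RULES:
        sub = per_arc[per_arc["label"] == label]
        if len(sub) >= 3:
            add("per_wobble_type", label, sub["copies"], sub["usage"])
    return pd.DataFrame(rows, columns=["level", "mode", "r", "p", "n", "degenerate"])
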
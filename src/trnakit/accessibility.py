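"""Transcriptional availability of tRNA genes from open-chromatin peaks.

A gene counts as available at a stage iff it is *fully embedded* in a single
peak of that stage (equality at both boundaries permitted); partial overlap
is not enough.  Strand is ignored -- accessibility is strandless.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repertoire import TrnaGene

logger = logging.getLogger(__name__)

CATEGORY_CONSTITUTIVE = "constitutive"
CATEGORY_PARTIAL = "partial"
CATEGORY_NEVER = "never"


@dataclass(frozen=True)
class Peak:
    """0-based half-open interval; extra BED columns are carried opaquely."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")


def read_bed(source) -> list:
    """Read BED3+ into peaks.  First three columns mandatory."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_bed(fh.readlines())
    peaks = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: BED needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed coordinates ({exc})") from None
        name = parts[3] if len(parts) > 3 else None
        score = None
        if len(parts) > 4:
            try:
                score = float(parts[4])
            except ValueError:
                score = None
        peaks.append(Peak(parts[0], start, end, name, score, tuple(parts[5:])))
    return peaks


def merge_peaks(peaks: Sequence[Peak]) -> list:
    """Optional preprocessing: merge overlapping/adjacent peaks per chromosome."""
    out = []
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ivs = sorted((p.start, p.end) for p in by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(Peak(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(Peak(chrom, cur_s, cur_e))
    return out


@dataclass
class AvailabilityMatrix:
    genes: tuple
    stages: tuple
    available: np.ndarray  # bool, genes x stages

    def __post_init__(self) -> None:
        self.available = np.asarray(self.available, dtype=bool)
        if self.available.shape != (len(self.genes), len(self.stages)):
            raise ValueError("availability matrix dimensions inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.available, index=list(self.genes), columns=list(self.stages))


class _ChromIndex:
    """Peaks sorted by start with a running max of ends: a gene [s, e) is
    embedded in some peak iff max{p.end : p.start <= s} >= e."""

    def __init__(self, peaks: Sequence[Peak]):
        ivs = sorted((p.start, p.end) for p in peaks)
        self.starts = [s for s, _ in ivs]
        self.maxend = list(np.maximum.accumulate([e for _, e in ivs])) if ivs else []

    def embeds(self, start0: int, end0: int) -> bool:
        i = bisect_right(self.starts, start0) - 1
        return i >= 0 and self.maxend[i] >= end0


def embed_classify(
    genes: Sequence[TrnaGene],
    peaks_by_stage: Mapping[str, Sequence[Peak]],
    merge: bool = False,
) -> AvailabilityMatrix:
    """Classify each gene as available per stage by the full-embedding rule."""
    stages = tuple(peaks_by_stage)
    mat = np.zeros((len(genes), len(stages)), dtype=bool)
    gene_chroms = {g.chrom for g in genes}
    for j, stage in enumerate(stages):
        peaks = peaks_by_stage[stage]
        if merge:
            peaks = merge_peaks(peaks)
        by_chrom: dict[str, list] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        index = {c: _ChromIndex(ps) for c, ps in by_chrom.items()}
        absent = gene_chroms - set(index)
        if absent:
            logger.warning(
                "stage %s: no peaks on chromosome(s) %s; genes there unavailable",
                stage, ",".join(sorted(absent)),
            )
        for i, g in enumerate(genes):
            idx = index.get(g.chrom)
            mat[i, j] = idx.embeds(g.start0, g.end0) if idx else False
    return AvailabilityMatrix(tuple(g.gene_id for g in genes), stages, mat)


@dataclass
class AvailabilitySummary:
    categories: pd.Series  # gene_id -> category string
    category_counts: dict
    combos: pd.DataFrame  # stage-set union/intersection counts
    isotype_proportions: pd.DataFrame | None = None


def _categorize(row: np.ndarray, stages: Sequence[str]) -> str:
    k = int(row.sum())
    if k == len(stages):
        return CATEGORY_CONSTITUTIVE
    if k == 0:
        return CATEGORY_NEVER
    if k == 1:
        return f"stage_specific:{stages[int(np.argmax(row))]}"
    return CATEGORY_PARTIAL


def availability_summary(
    m: AvailabilityMatrix,
    isotypes: Mapping[str, str] | None = None,
) -> AvailabilitySummary:
    """Category table plus union/intersection counts per stage combination.

    constitutive = available at all stages; stage_specific:<stage> = exactly
    that one; partial = some but not all (>= 2); never = none.  For every
    non-empty stage subset S, union counts genes available in >= 1 member of
    S and intersection counts genes available in all members.
    """
    cats = pd.Series(
        [_categorize(m.available[i], m.stages) for i in range(len(m.genes))],
        index=list(m.genes),
        name="category",
    )
    counts = cats.value_counts().to_dict()
    combo_rows = []
    for k in range(1, len(m.stages) + 1):
        for combo in combinations(range(len(m.stages)), k):
            sub = m.available[:, list(combo)]
            combo_rows.append(
                {
                    "stages": "+".join(m.stages[i] for i in combo),
                    "n_stages": k,
                    "union": int(sub.any(axis=1).sum()),
                    "intersection": int(sub.all(axis=1).sum()),
                }
            )
    combos = pd.DataFrame(combo_rows)
    iso_prop = None
    if isotypes is not None:
        df = pd.DataFrame({"category": cats, "isotype": [isotypes.get(g, "NA") for g in m.genes]})
        tab = df.value_counts(["isotype", "category"]).rename("n").reset_index()
        tab["proportion"] = tab.groupby("isotype")["n"].transform(lambda s: s / s.sum())
        iso_prop = tab.sort_values(["isotype", "category"], ignore_index=True)
    return AvailabilitySummary(cats, counts, combos, iso_prop)
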
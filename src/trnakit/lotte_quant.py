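"""Mature-tRNA quantification: masking, read routing, alignment validation
and cluster counting.

Alignment itself is external; this stage consumes plain-text SAM records and
re-applies the validity filters:

(i)   uniquely mapped (NH-like multiplicity == 1),
(ii)  leftmost mapping position strictly after the artificial 5' flank,
(iii) the stored read sequence ends with CCA,
(iv)  the alignment extends to the final base of the cluster reference.

Criterion (iii) is evaluated on the read sequence as stored (post-trim), so
a soft-clipped CCA fails (iv) rather than (iii).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repertoire import IsodecoderCluster, TrnaGene

logger = logging.getLogger(__name__)

CRITERIA = ("unique", "past_flank", "cca_end", "reaches_3prime")

SHORT_MIN = 8   # reads below this are discarded
LONG_MIN = 22   # short reads are [SHORT_MIN, LONG_MIN); long are >= LONG_MIN

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


def mask_genome(genome: Mapping[str, str], genes: Sequence[TrnaGene]) -> dict:
    """Hard-mask every gene interval with N; everything else untouched.
    Idempotent by construction."""
    out = {chrom: list(seq) for chrom, seq in genome.items()}
    for g in genes:
        if g.chrom not in out:
            raise ValueError(f"{g.gene_id}: chromosome {g.chrom!r} not in genome")
        contig = out[g.chrom]
        if g.start < 1 or g.end > len(contig):
            raise ValueError(f"{g.gene_id}: interval outside {g.chrom}")
        contig[g.start - 1 : g.end] = "N" * g.length
    return {chrom: "".join(seq) for chrom, seq in out.items()}


@dataclass
class LengthSplit:
    short: list
    long: list
    discarded: list

    @property
    def counts(self) -> dict:
        return {
            "short": len(self.short),
            "long": len(self.long),
            "discarded": len(self.discarded),
        }


def split_by_length(reads: Iterable) -> LengthSplit:
    """Partition (id, sequence) reads into short (8-21 nt), long (>= 22 nt)
    and discarded (< 8 nt)."""
    split = LengthSplit([], [], [])
    for rec in reads:
        _rid, seq = rec
        n = len(seq)
        if n < SHORT_MIN:
            split.discarded.append(rec)
        elif n < LONG_MIN:
            split.short.append(rec)
        else:
            split.long.append(rec)
    return split


@dataclass(frozen=True)
class AlignmentRecord:
    query: str
    ref: str
    pos: int              # leftmost aligned reference position, 1-based
    aln_span: int         # reference positions consumed
    multiplicity: int     # NH-like reported-hit count
    read_seq: str
    mapped: bool
    route: str = ""       # provenance (e.g. "long"/"short" pass), not re-derived


def _cigar_ref_span(cigar: str) -> int:
    if cigar == "*":
        return 0
    span = 0
    consumed = 0
    for n, op in _CIGAR_RE.findall(cigar):
        consumed += len(n) + 1
        if op in _REF_CONSUMING:
            span += int(n)
    if consumed != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return span


def parse_sam(source) -> list:
    """Parse uncompressed SAM text into alignment records.

    The header is optional.  Multiplicity comes from the NH tag when present
    and is otherwise inferred as 1 (warned once per stream).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_sam(fh.readlines())
    records = []
    warned_nh = False
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        parts = line.split("\t")
        if len(parts) < 11:
            raise ValueError(f"line {lineno}: SAM record needs >= 11 fields")
        qname, flag, rname, pos, _mapq, cigar = parts[0], int(parts[1]), parts[2], int(parts[3]), parts[4], parts[5]
        seq = parts[9]
        mapped = not (flag & 0x4) and rname != "*"
        nh = None
        for tag in parts[11:]:
            if tag.startswith("NH:i:"):
                nh = int(tag[5:])
                break
        if nh is None:
            if mapped and not warned_nh:
                logger.warning("line %d: NH tag absent; multiplicity inferred as 1", lineno)
                warned_nh = True
            nh = 1
        records.append(
            AlignmentRecord(
                query=qname,
                ref=rname,
                pos=pos,
                aln_span=_cigar_ref_span(cigar),
                multiplicity=nh,
                read_seq=seq,
                mapped=mapped,
            )
        )
    return records


@dataclass(frozen=True)
class ValidationVerdict:
    valid: bool
    failed_criteria: frozenset

    def __post_init__(self) -> None:
        if self.valid != (not self.failed_criteria):
            raise ValueError("valid flag inconsistent with failed_criteria")


def validate_read(rec: AlignmentRecord, ref: IsodecoderCluster) -> ValidationVerdict:
    """Apply criteria (i)-(iv) against the cluster reference.

    (ii) is read strictly: the first aligned base must sit at reference
    position flank_len + 1 or later, so an alignment touching the flank
    fails.  (iv) requires the alignment to end on the final reference base
    (the last A of the appended CCA).
    """
    if not rec.mapped:
        raise ValueError(f"{rec.query}: unmapped record; filter upstream")
    if rec.ref != ref.cluster_id:
        raise ValueError(f"{rec.query}: aligned to {rec.ref!r}, not {ref.cluster_id!r}")
    failed = set()
    if rec.multiplicity != 1:
        failed.add("unique")
    if rec.pos < ref.flank_len + 1:
        failed.add("past_flank")
    if not rec.read_seq.endswith("CCA"):
        failed.add("cca_end")
    if rec.pos + rec.aln_span - 1 != len(ref.reference_seq):
        failed.add("reaches_3prime")
    return ValidationVerdict(valid=not failed, failed_criteria=frozenset(failed))


@dataclass
class CountReport:
    counts: pd.Series            # cluster_id -> valid-read count
    n_valid: int
    n_invalid: int
    failure_histogram: dict      # criterion -> number of reads failing it
    verdicts: pd.DataFrame       # per-read: query, ref, valid, failed


def count_clusters(
    records: Iterable, clusters: Sequence[IsodecoderCluster]
) -> CountReport:
    """Count valid reads per cluster; invalid reads are tallied by failure
    reason.  A mapped record referencing an unknown cluster is an error."""
    by_id = {c.cluster_id: c for c in clusters}
    counts = {c.cluster_id: 0 for c in clusters}
    hist = {c: 0 for c in CRITERIA}
    rows = []
    n_valid = n_invalid = 0
    for rec in records:
        if not rec.mapped:
            continue
        cluster = by_id.get(rec.ref)
        if cluster is None:
            raise KeyError(f"{rec.query}: unknown cluster reference {rec.ref!r}")
        verdict = validate_read(rec, cluster)
        if verdict.valid:
            counts[rec.ref] += 1
            n_valid += 1
        else:
            n_invalid += 1
            for c in verdict.failed_criteria:
                hist[c] += 1
        rows.append(
            (rec.query, rec.ref, verdict.valid, ",".join(sorted(verdict.failed_criteria)))
        )
    return CountReport(
        counts=pd.Series(counts, name="count"),
        n_valid=n_valid,
        n_invalid=n_invalid,
        failure_histogram=hist,
        verdicts=pd.DataFrame(rows, columns=["query", "ref", "valid", "failed"]),
    )


def aggregate_counts(
    counts: pd.DataFrame | pd.Series, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Sum feature x sample counts within groups (isoacceptor or isotype).

    ``grouping`` must cover every feature; per-sample column totals are
    conserved by construction.
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_frame()
    missing = [f for f in counts.index if f not in grouping]
    if missing:
        raise KeyError(f"features without a group: {missing}")
    groups = pd.Series({f: grouping[f] for f in counts.index}, name="group")
    out = counts.groupby(groups).sum()
    out.index.name = None
    return out.sort_index()


def cluster_group_maps(
    clusters: Sequence[IsodecoderCluster], genes: Sequence[TrnaGene]
) -> tuple:
    """(cluster -> anticodon, cluster -> isotype) derived from member genes.

    Members of one cluster share a mature sequence, hence anticodon and
    isotype; the representative's annotation is used.
    """
    by_gene = {g.gene_id: g for g in genes}
    to_anticodon = {}
    to_isotype = {}
    for c in clusters:
        g = by_gene[c.representative]
        to_anticodon[c.cluster_id] = g.anticodon
        to_isotype[c.cluster_id] = g.isotype
    return to_anticodon, to_isotype
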
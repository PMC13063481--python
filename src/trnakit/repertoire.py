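"""tRNA gene repertoire: prediction parsing, clustering and localization test.

Internal coordinates are 1-based inclusive (the gene-predictor dialect);
minus-strand records are normalized so that start <= end.  BED conversion
happens at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import AA_3TO1, is_dna, revcomp

logger = logging.getLogger(__name__)

#: isotype labels accepted without a warning
KNOWN_ISOTYPES = frozenset(AA_3TO1) | {"iMet", "fMet", "SeC", "Sec", "Sup", "Undet"}

#: gene-length plausibility window (predictor output sanity check)
GENE_LENGTH_WINDOW = (60, 120)
#: mature-length plausibility window
MATURE_LENGTH_WINDOW = (69, 87)

FLANK_LEN = 10


@dataclass(frozen=True)
class TrnaGene:
    """One predicted tRNA gene (1-based inclusive genomic coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str  # 3-mer or "unknown"
    introns: tuple = ()
    pseudogene: bool = False
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end after normalization")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.introns:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"{self.gene_id}: intron ({s},{e}) outside gene "
                    f"[{self.start},{self.end}]"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end."""
        return self.end

    @property
    def has_anticodon(self) -> bool:
        return self.anticodon != "unknown"


def _normalize_interval(a: int, b: int) -> tuple:
    return (a, b) if a <= b else (b, a)


def parse_trnascan(source) -> list:
    """Parse tRNAscan-SE style tabular output into :class:`TrnaGene` records.

    ``source`` may be a path or an iterable of lines.  Header lines are
    tolerated; reversed coordinates denote the minus strand and are swapped.
    Pseudogene notes and undetermined anticodons are preserved.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_trnascan(fh.readlines())
    genes = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        first = line.split()[0]
        if first in ("Sequence", "Name") or set(first) <= {"-"}:
            continue
        parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split())]
        parts = [p for p in parts if p != ""]
        if len(parts) < 9:
            raise ValueError(f"line {lineno}: expected >= 9 fields, got {len(parts)}")
        name, num = parts[0], parts[1]
        try:
            begin, end = int(parts[2]), int(parts[3])
            intron_b, intron_e = int(parts[6]), int(parts[7])
            score = float(parts[8])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
        isotype = parts[4]
        anticodon = parts[5].upper()
        note = " ".join(parts[9:]) if len(parts) > 9 else ""

        strand = "+" if begin <= end else "-"
        start, stop = _normalize_interval(begin, end)
        introns: tuple = ()
        if intron_b or intron_e:
            introns = (_normalize_interval(intron_b, intron_e),)
        if isotype not in KNOWN_ISOTYPES:
            logger.warning("line %d: unknown isotype symbol %r (record kept)", lineno, isotype)
        if not (is_dna(anticodon) and len(anticodon) == 3):
            anticodon = "unknown"
        gene = TrnaGene(
            gene_id=f"{name}.trna{num}",
            chrom=name,
            start=start,
            end=stop,
            strand=strand,
            isotype=isotype,
            anticodon=anticodon,
            introns=introns,
            pseudogene="pseudo" in note.lower(),
            score=score,
        )
        lo, hi = GENE_LENGTH_WINDOW
        if not (lo <= gene.length <= hi):
            logger.warning(
                "line %d: gene %s length %d outside [%d, %d]",
                lineno, gene.gene_id, gene.length, lo, hi,
            )
        genes.append(gene)
    return genes


def extract_mature(gene: TrnaGene, genome: Mapping[str, str]) -> str:
    """Coding-strand mature sequence: introns excised, minus strand
    reverse-complemented.  The post-transcriptional CCA is *not* appended."""
    if gene.chrom not in genome:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    contig = genome[gene.chrom]
    if gene.end > len(contig) or gene.start < 1:
        raise ValueError(
            f"{gene.gene_id}: [{gene.start},{gene.end}] outside {gene.chrom} "
            f"(length {len(contig)})"
        )
    seq = contig[gene.start - 1 : gene.end]
    for s, e in sorted(gene.introns, reverse=True):
        seq = seq[: s - gene.start] + seq[e - gene.start + 1 :]
    if gene.strand == "-":
        seq = revcomp(seq)
    lo, hi = MATURE_LENGTH_WINDOW
    if not (lo <= len(seq) <= hi):
        logger.warning(
            "%s: mature length %d outside plausibility window [%d, %d]",
            gene.gene_id, len(seq), lo, hi,
        )
    return seq.upper()


@dataclass(frozen=True)
class IsodecoderCluster:
    """Genes with identical mature sequences plus their artificial reference.

    ``reference_seq`` is flank(10) + mature + "CCA"; the flank is the 10 nt
    immediately 5' of the representative gene on its coding strand.
    """

    cluster_id: str
    mature_seq: str
    members: tuple
    representative: str
    reference_seq: str
    flank_len: int = FLANK_LEN

    def __post_init__(self) -> None:
        if len(self.reference_seq) != self.flank_len + len(self.mature_seq) + 3:
            raise ValueError(f"{self.cluster_id}: reference length inconsistent")
        if not self.reference_seq.endswith("CCA"):
            raise ValueError(f"{self.cluster_id}: reference does not end with CCA")


def _upstream_flank(gene: TrnaGene, genome: Mapping[str, str], flank_len: int) -> str:
    contig = genome[gene.chrom]
    if gene.strand == "+":
        lo = gene.start - 1 - flank_len
        flank = contig[max(lo, 0) : gene.start - 1]
        if lo < 0:
            logger.warning("%s: flank truncated at contig start, padded with N", gene.gene_id)
            flank = "N" * (-lo) + flank
    else:
        hi = gene.end + flank_len
        flank = contig[gene.end : min(hi, len(contig))]
        if hi > len(contig):
            logger.warning("%s: flank truncated at contig end, padded with N", gene.gene_id)
            flank = flank + "N" * (hi - len(contig))
        flank = revcomp(flank)
    return flank.upper()


def cluster_isodecoders(
    genes: Sequence[TrnaGene],
    genome: Mapping[str, str],
    flank_len: int = FLANK_LEN,
) -> list:
    """Cluster genes by identical mature sequence.

    The representative (flank donor) is the lexicographically smallest
    gene_id of the cluster -- a deterministic stand-in for an arbitrary
    choice.  Clusters are sorted by mature sequence and numbered from 1.
    """
    by_gene = {g.gene_id: g for g in genes}
    groups: dict[str, list] = {}
    for g in genes:
        groups.setdefault(extract_mature(g, genome), []).append(g.gene_id)
    clusters = []
    for i, mature in enumerate(sorted(groups), start=1):
        members = tuple(sorted(groups[mature]))
        rep = members[0]
        flank = _upstream_flank(by_gene[rep], genome, flank_len)
        clusters.append(
            IsodecoderCluster(
                cluster_id=f"cluster{i}",
                mature_seq=mature,
                members=members,
                representative=rep,
                reference_seq=flank + mature + "CCA",
                flank_len=flank_len,
            )
        )
    return clusters


def _isotype_label(gene: TrnaGene, merge_imet: bool) -> str:
    if merge_imet and gene.isotype in ("iMet", "fMet"):
        return "Met"
    return gene.isotype


@dataclass
class RepertoireSummary:
    n_genes: int
    n_isodecoders: int | None
    n_isoacceptors: int
    n_isotypes: int
    gene_density: pd.Series | None
    anticodon_breakdown: pd.DataFrame

    @property
    def counts(self) -> tuple:
        return (self.n_genes, self.n_isodecoders, self.n_isoacceptors, self.n_isotypes)


def summarize_repertoire(
    genes: Sequence[TrnaGene],
    clusters: Sequence[IsodecoderCluster] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    merge_imet: bool = True,
) -> RepertoireSummary:
    """Counts at gene / isodecoder / isoacceptor / isotype level.

    Genes with an undetermined anticodon contribute to the gene-level count
    only.  Initiator-methionine labels are folded into Met for the isotype
    tally (so the isotype count matches one-per-amino-acid conventions).
    Density is genes per Mb when chromosome sizes are supplied.
    """
    with_ac = [g for g in genes if g.has_anticodon]
    breakdown = (
        pd.DataFrame(
            [(_isotype_label(g, merge_imet), g.anticodon) for g in with_ac],
            columns=["isotype", "anticodon"],
        )
        .value_counts()
        .rename("n_genes")
        .reset_index()
        .sort_values(["isotype", "anticodon"], ignore_index=True)
    )
    density = None
    if chrom_sizes is not None:
        per_chrom = pd.Series(
            pd.Categorical([g.chrom for g in genes], categories=sorted(chrom_sizes))
        ).value_counts().sort_index()
        density = per_chrom / (pd.Series(chrom_sizes).sort_index() / 1e6)
        density.name = "genes_per_mb"
    return RepertoireSummary(
        n_genes=len(genes),
        n_isodecoders=len(clusters) if clusters is not None else None,
        n_isoacceptors=len({g.anticodon for g in with_ac}),
        n_isotypes=len({_isotype_label(g, merge_imet) for g in with_ac}),
        gene_density=density,
        anticodon_breakdown=breakdown,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-chromosome multivariate hypergeometric localization test."""

    chrom: str
    observed: tuple  # isotype counts, ordered like `isotypes`
    isotypes: tuple
    n_draws: int
    statistic: float  # point log-pmf of the observed vector
    p_value: float
    seed: int
    degenerate: bool = False


# float tolerance when comparing log-pmf values (tie handling)
_LOGPMF_TIE_EPS = 1e-9


def chrom_isotype_test(
    genes: Sequence[TrnaGene],
    n_draws: int = 10_000,
    seed: int | None = None,
) -> list:
    """Monte-Carlo multivariate hypergeometric test of isotype localization.

    For each chromosome with ``n_c`` genes the null draws ``n_c`` genes
    without replacement from the genome-wide isotype pool; the test statistic
    is the point pmf of the drawn composition, and the p-value is the
    add-one-corrected fraction of draws at least as extreme (pmf <= observed
    pmf).  Deterministic given (genes, n_draws, seed).
    """
    if seed is None:
        raise ValueError("seed is mandatory for the Monte-Carlo test")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    chroms = sorted({g.chrom for g in genes})
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes")
    isotypes = tuple(sorted({g.isotype for g in genes}))
    counts = pd.DataFrame(0, index=chroms, columns=list(isotypes), dtype=int)
    for g in genes:
        counts.loc[g.chrom, g.isotype] += 1
    pool = counts.sum(axis=0).to_numpy()

    rng = np.random.default_rng(seed)
    results = []
    degenerate = len(isotypes) < 2
    for chrom in chroms:
        observed = counts.loc[chrom].to_numpy()
        n_c = int(observed.sum())
        if degenerate or n_c == 0:
            results.append(
                EnrichmentResult(
                    chrom, tuple(observed), isotypes, n_draws,
                    statistic=0.0, p_value=1.0, seed=seed, degenerate=True,
                )
            )
            continue
        dist = stats.multivariate_hypergeom(m=pool, n=n_c)
        obs_lp = float(dist.logpmf(observed))
        draws = rng.multivariate_hypergeometric(pool, n_c, size=n_draws)
        draw_lp = dist.logpmf(draws)
        b = int(np.sum(draw_lp <= obs_lp + _LOGPMF_TIE_EPS))
        results.append(
            EnrichmentResult(
                chrom, tuple(int(x) for x in observed), isotypes, n_draws,
                statistic=obs_lp, p_value=(b + 1) / (n_draws + 1), seed=seed,
            )
        )
    return results


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (used by the optional multiplicity switch)."""
    from statsmodels.stats.multitest import multipletests

    if len(pvalues) == 0:
        return np.array([])
    return multipletests(pvalues, method="holm")[1]


# ---------------------------------------------------------------------------
# writers

def write_cluster_fasta(clusters: Sequence[IsodecoderCluster], path) -> None:
    from .fasta import write_fasta

    write_fasta({c.cluster_id: c.reference_seq for c in clusters}, path)


def write_membership_tsv(clusters: Sequence[IsodecoderCluster], path) -> None:
    rows = [
        (c.cluster_id, m, c.representative, len(c.mature_seq))
        for c in clusters
        for m in c.members
    ]
    pd.DataFrame(
        rows, columns=["cluster_id", "gene_id", "representative", "mature_length"]
    ).to_csv(path, sep="\t", index=False)
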
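"""Seeded synthetic inputs with planted ground truth for every stage.

One global seed fans out into independent per-generator substreams
(SeedSequence spawning), so each stage can be regenerated on its own without
perturbing the others.  Every generator is a pure function of its config:
reruns with the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accessibility import Peak
from .genetic_code import AA_1TO3, STANDARD_CODE, codon_of, revcomp
from .repertoire import IsodecoderCluster, TrnaGene
from .wobble_graph import DecodingPotentialGraph

_BASES = np.array(list("ACGT"))
_STREAMS = ("genome", "cds", "peaks", "lotte", "counts")

DEFAULT_STAGES = ("vegetative", "streaming", "mound", "fruiting")


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all generators; only ``seed`` is mandatory."""

    seed: int
    # genome / repertoire
    n_chroms: int = 6
    chrom_length: int = 60_000
    chrom_lengths: tuple | None = None
    n_genes: int = 400
    isotype_weights: Mapping[str, float] | None = None
    chrom_skew: Mapping[tuple, float] = field(default_factory=dict)
    intron_prob: float = 0.1
    intron_len: tuple = (8, 15)
    pseudogene_fraction: float = 0.02
    duplication: float = 0.8  # chance a gene reuses an existing mature sequence
    anticodons_per_isotype: int = 2
    # CDS
    n_cds: int = 2_000
    cds_codons: tuple = (80, 400)
    wobble_skew: float = 0.0
    total_codon_mass: int = 50_000
    # peaks
    stages: tuple = DEFAULT_STAGES
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.7,
            "stage_specific": 0.05,
            "partial": 0.15,
            "never": 0.10,
        }
    )
    peak_margin: tuple = (5, 40)
    decoy_fraction: float = 0.5
    n_background_peaks: int = 50
    # LOTTE reads
    n_reads: int = 50_000
    failure_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "non_unique": 0.05,
            "in_flank": 0.05,
            "non_cca": 0.05,
            "short_3prime": 0.05,
        }
    )
    short_read_fraction: float = 0.1
    # counts / DE
    n_features: int = 60
    n_replicates: int = 3
    base_mean: float = 200.0
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_lfc: float = 2.5
    masking_motif: bool = True

    def __post_init__(self) -> None:
        for name in (
            "intron_prob", "pseudogene_fraction", "duplication", "wobble_skew",
            "decoy_fraction", "short_read_fraction", "de_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if sum(self.failure_fractions.values()) > 1.0:
            raise ValueError("failure fractions sum above 1")
        fr = self.category_fractions
        if abs(sum(fr.values()) - 1.0) > 1e-9 or any(v < 0 for v in fr.values()):
            raise ValueError("category fractions must be non-negative and sum to 1")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# genome & repertoire


def _isotype_anticodon_pools(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Restricted per-isotype anticodon repertoire (expanded limited set)."""
    by_iso: dict[str, list] = {}
    for anti in sorted(STANDARD_CODE.sense_anticodons):
        by_iso.setdefault(AA_1TO3[STANDARD_CODE.anticodon_aa(anti)], []).append(anti)
    pools = {}
    for iso in sorted(by_iso):
        opts = by_iso[iso]
        k = min(cfg.anticodons_per_isotype, len(opts))
        pools[iso] = sorted(rng.choice(opts, size=k, replace=False))
    return pools


def synth_gene_table(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plan of genes (no sequence yet): chromosome, isotype, anticodon,
    lengths, strand, intron and pseudogene flags, sequence-pool label."""
    rng = rng if rng is not None else _rng(cfg, "genome")
    lengths = cfg.chrom_lengths or tuple([cfg.chrom_length] * cfg.n_chroms)
    chroms = [f"chr{i + 1}" for i in range(len(lengths))]
    iso_pools = _isotype_anticodon_pools(cfg, rng)
    isotypes = sorted(iso_pools)
    base_w = np.array(
        [cfg.isotype_weights.get(i, 0.0) if cfg.isotype_weights else 1.0 for i in isotypes],
        dtype=float,
    )
    if base_w.sum() == 0:
        raise ValueError("isotype weights sum to zero")
    chrom_p = np.asarray(lengths, dtype=float) / sum(lengths)

    seq_pool: dict[str, list] = {}
    rows = []
    for i in range(cfg.n_genes):
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        w = base_w * np.array(
            [cfg.chrom_skew.get((chrom, iso), 1.0) for iso in isotypes]
        )
        iso = isotypes[rng.choice(len(isotypes), p=w / w.sum())]
        anticodon = iso_pools[iso][rng.integers(0, len(iso_pools[iso]))]
        pool = seq_pool.setdefault(anticodon, [])
        if pool and rng.random() < cfg.duplication:
            label = pool[rng.integers(0, len(pool))]
            mature_len = int(label.split(":")[-1])
        else:
            mature_len = int(rng.integers(69, 88))
            label = f"{anticodon}:{len(pool)}:{mature_len}"
            pool.append(label)
        intron = 0
        if rng.random() < cfg.intron_prob:
            cap = min(cfg.intron_len[1], 95 - mature_len)
            if cap >= cfg.intron_len[0]:
                intron = int(rng.integers(cfg.intron_len[0], cap + 1))
        rows.append(
            {
                "chrom": chrom,
                "isotype": iso,
                "anticodon": anticodon,
                "mature_len": mature_len,
                "intron_len": intron,
                "strand": "+" if rng.random() < 0.5 else "-",
                "pseudogene": bool(rng.random() < cfg.pseudogene_fraction),
                "seq_label": label,
                "score": float(np.round(rng.uniform(50, 90), 1)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SynthGenome:
    genome: dict
    genes: list
    truth: pd.DataFrame


def synth_genome(cfg: SimConfig) -> SynthGenome:
    """Genome FASTA dict + gene records + truth table.

    Genes are placed without overlap; mature lengths fall in 69-87 and
    intron insertion extends the genomic gene up to 95.  Raises with advice
    when the requested genes cannot be placed.
    """
    rng = _rng(cfg, "genome")
    plan = synth_gene_table(cfg, rng)
    lengths = dict(
        zip(
            [f"chr{i + 1}" for i in range(len(cfg.chrom_lengths or [0] * cfg.n_chroms))],
            cfg.chrom_lengths or [cfg.chrom_length] * cfg.n_chroms,
        )
    )
    genome = {c: _random_dna(rng, n) for c, n in lengths.items()}
    pool_seqs: dict[str, str] = {}
    genes: list[TrnaGene] = []
    truth_rows = []
    for chrom in sorted(lengths):
        sub = plan[plan["chrom"] == chrom]
        glens = (sub["mature_len"] + sub["intron_len"]).to_numpy()
        free = lengths[chrom] - int(glens.sum())
        if free < len(sub):
            raise ValueError(
                f"{chrom}: cannot place {len(sub)} genes in {lengths[chrom]} bp; "
                "increase chrom_length or reduce n_genes"
            )
        offsets = np.sort(rng.integers(0, free + 1, size=len(sub)))
        cursor = np.concatenate([[0], np.cumsum(glens)[:-1]])
        starts = offsets + cursor + 1  # 1-based
        contig = list(genome[chrom])
        for (row_idx, row), start in zip(sub.iterrows(), starts):
            label = row["seq_label"]
            if label not in pool_seqs:
                pool_seqs[label] = _random_dna(rng, row["mature_len"])
            mature = pool_seqs[label]
            il = int(row["intron_len"])
            end = int(start) + len(mature) + il - 1
            introns: tuple = ()
            if il:
                k = int(rng.integers(max(10, 1), len(mature) - 9))
                region = mature[:k] + _random_dna(rng, il) + mature[k:]
                if row["strand"] == "+":
                    introns = ((int(start) + k, int(start) + k + il - 1),)
                else:
                    introns = ((end - k - il + 1, end - k),)
            else:
                region = mature
            placed = region if row["strand"] == "+" else revcomp(region)
            contig[int(start) - 1 : end] = placed
            gene_id = f"{chrom}.trna{row_idx + 1}"
            genes.append(
                TrnaGene(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=end,
                    strand=row["strand"],
                    isotype=row["isotype"],
                    anticodon=row["anticodon"],
                    introns=introns,
                    pseudogene=bool(row["pseudogene"]),
                    score=float(row["score"]),
                )
            )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": int(start),
                    "end": end,
                    "strand": row["strand"],
                    "isotype": row["isotype"],
                    "anticodon": row["anticodon"],
                    "pseudogene": bool(row["pseudogene"]),
                    "mature_seq": mature,
                    "seq_label": label,
                    "intron_len": il,
                }
            )
        genome[chrom] = "".join(contig)
    genes.sort(key=lambda g: g.gene_id)
    truth = pd.DataFrame(truth_rows).sort_values("gene_id", ignore_index=True)
    return SynthGenome(genome=genome, genes=genes, truth=truth)


def write_trnascan_table(genes: Sequence[TrnaGene], path) -> None:
    """Emit predictor-style tabular output (reversed coordinates on minus
    strand, intron columns, pseudo note)."""
    with open(path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\t\n")
        fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n")
        fh.write("--------\t------\t-----\t----\t----\t-----\t-----\t----\t------\t------\n")
        for g in genes:
            num = g.gene_id.rsplit("trna", 1)[-1]
            b, e = (g.start, g.end) if g.strand == "+" else (g.end, g.start)
            if g.introns:
                ib, ie = g.introns[0]
                if g.strand == "-":
                    ib, ie = ie, ib
            else:
                ib = ie = 0
            note = "pseudo" if g.pseudogene else ""
            fh.write(
                f"{g.chrom}\t{num}\t{b}\t{e}\t{g.isotype}\t{g.anticodon}\t"
                f"{ib}\t{ie}\t{g.score}\t{note}\n"
            )


# ---------------------------------------------------------------------------
# CDS with codon usage tied (or not) to the wobble graph


def synth_copy_number(
    cfg: SimConfig, graph: DecodingPotentialGraph, mode: str = "wobble_skew"
) -> dict:
    """Anticodon copy-number table.

    ``wobble_skew`` places all copies on compensating anticodons (wobble
    bases G and T -- the arc sources), leaving their targets at zero copies;
    ``plain`` spreads copies over a random half of all anticodons.
    """
    rng = _rng(cfg, "cds")
    if mode == "wobble_skew":
        carriers = [v for v in graph.vertices if v[0] in ("G", "T")]
    elif mode == "plain":
        verts = list(graph.vertices)
        carriers = sorted(rng.choice(verts, size=len(verts) // 2, replace=False))
    else:
        raise ValueError(f"unknown copy-number mode {mode!r}")
    return {a: int(np.ceil(rng.lognormal(2.0, 0.8))) for a in carriers}


def codon_probabilities(
    cfg: SimConfig,
    copy_number: Mapping[str, float],
    graph: DecodingPotentialGraph,
) -> pd.Series:
    """Codon sampling distribution: a (1 - skew)/skew blend of exact-cognate
    copy numbers and graph-compensator copy numbers."""
    eps = 0.01
    codons = sorted(graph.code.sense_codons)
    exact = np.array([copy_number.get(revcomp(c), 0) + eps for c in codons])
    comp_mass = {v: eps for v in graph.vertices}
    for a in graph.arcs:
        comp_mass[a.target] += copy_number.get(a.source, 0)
    compensated = np.array([comp_mass[revcomp(c)] for c in codons])
    p = (1 - cfg.wobble_skew) * exact / exact.sum() + cfg.wobble_skew * compensated / compensated.sum()
    return pd.Series(p / p.sum(), index=codons)


def synth_cds(
    cfg: SimConfig,
    copy_number: Mapping[str, float],
    graph: DecodingPotentialGraph,
) -> tuple:
    """CDS records (id, seq) plus the codon distribution they were drawn
    from.  Lengths are multiples of 3; a stop is appended, never internal."""
    rng = _rng(cfg, "cds")
    rng.random()  # keep the stream distinct from synth_copy_number reruns
    probs = codon_probabilities(cfg, copy_number, graph)
    codons = np.array(probs.index)
    per_cds = rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1, size=cfg.n_cds)
    total = int(per_cds.sum())
    scale = min(1.0, cfg.total_codon_mass / max(total, 1))
    records = []
    for i, n in enumerate(per_cds):
        n = max(3, int(n * scale))
        seq = "".join(rng.choice(codons, size=n, p=probs.to_numpy())) + "TAA"
        records.append((f"cds{i + 1}", seq))
    return records, probs


# ---------------------------------------------------------------------------
# peaks with planted availability categories


def synth_peaks(cfg: SimConfig, genes: Sequence[TrnaGene]) -> tuple:
    """Per-stage peak lists + per-gene availability truth.

    Planted categories: constitutive / stage_specific / partial / never.
    Never-genes may receive a partial-overlap decoy peak that must be
    rejected by the full-embedding rule; background peaks are kept shorter
    than any gene so they can never embed one.
    """
    rng = _rng(cfg, "peaks")
    stages = cfg.stages
    cats = sorted(cfg.category_fractions)
    probs = np.array([cfg.category_fractions[c] for c in cats])
    peaks: dict[str, list] = {s: [] for s in stages}
    truth_rows = []
    for g in genes:
        cat = cats[rng.choice(len(cats), p=probs)]
        if cat == "constitutive":
            avail = set(stages)
        elif cat == "stage_specific":
            stage = stages[rng.integers(0, len(stages))]
            avail = {stage}
            cat = f"stage_specific:{stage}"
        elif cat == "partial":
            k = int(rng.integers(2, len(stages)))
            avail = set(rng.choice(stages, size=k, replace=False))
        else:
            avail = set()
        for s in stages:
            if s in avail:
                m1 = int(rng.integers(*cfg.peak_margin))
                m2 = int(rng.integers(*cfg.peak_margin))
                peaks[s].append(Peak(g.chrom, max(0, g.start0 - m1), g.end0 + m2))
        if not avail and rng.random() < cfg.decoy_fraction:
            s = stages[rng.integers(0, len(stages))]
            mid = g.start0 + g.length // 2
            peaks[s].append(Peak(g.chrom, mid, g.end0 + int(rng.integers(*cfg.peak_margin))))
        truth_rows.append(
            {"gene_id": g.gene_id, "category": cat, **{s: s in avail for s in stages}}
        )
    chroms = sorted({g.chrom for g in genes})
    max_pos = {c: max(g.end0 for g in genes if g.chrom == c) for c in chroms}
    for _ in range(cfg.n_background_peaks):
        c = chroms[rng.integers(0, len(chroms))]
        width = int(rng.integers(30, 61))  # < minimum gene length: cannot embed
        start = int(rng.integers(0, max_pos[c] + 1000))
        s = stages[rng.integers(0, len(stages))]
        peaks[s].append(Peak(c, start, start + width))
    truth = pd.DataFrame(truth_rows)
    return peaks, truth


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            name = p.name or "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\n")


# ---------------------------------------------------------------------------
# LOTTE-style alignments with per-read truth


def synth_lotte(cfg: SimConfig, clusters: Sequence[IsodecoderCluster]) -> tuple:
    """SAM text (with header) + per-read truth labels.

    Valid reads satisfy all four criteria; each failure category violates
    exactly one criterion so verdicts can be scored per-criterion.
    """
    rng = _rng(cfg, "lotte")
    cats = sorted(cfg.failure_fractions)
    p_fail = np.array([cfg.failure_fractions[c] for c in cats])
    p = np.concatenate([[1.0 - p_fail.sum()], p_fail])
    labels = ["valid"] + cats
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in clusters:
        lines.append(f"@SQ\tSN:{c.cluster_id}\tLN:{len(c.reference_seq)}")
    truth_rows = []
    for i in range(cfg.n_reads):
        c = clusters[rng.integers(0, len(clusters))]
        ref = c.reference_seq
        L = len(ref)
        category = labels[rng.choice(len(labels), p=p)]
        nh = 1
        if rng.random() < cfg.short_read_fraction:
            span = int(rng.integers(SPAN_SHORT[0], SPAN_SHORT[1] + 1))
            length_class = "short"
        else:
            span = int(rng.integers(SPAN_LONG[0], min(SPAN_LONG[1], L - 13) + 1))
            length_class = "long"
        if category == "in_flank":
            pos = int(rng.integers(1, c.flank_len + 1))
            seq = ref[pos - 1 :]
            span = L - pos + 1
        elif category == "short_3prime":
            end = L - 3
            pos = end - span + 1
            seq = ref[pos - 1 : end - 3] + "CCA"
        else:
            pos = L - span + 1
            seq = ref[pos - 1 :]
            if category == "non_unique":
                nh = 2
            elif category == "non_cca":
                seq = seq[:-3] + "TAG"
        failed = {
            "valid": "",
            "non_unique": "unique",
            "in_flank": "past_flank",
            "non_cca": "cca_end",
            "short_3prime": "reaches_3prime",
        }[category]
        qname = f"read{i + 1:06d}"
        lines.append(
            f"{qname}\t0\t{c.cluster_id}\t{pos}\t255\t{len(seq)}M\t*\t0\t0\t{seq}\t*\tNH:i:{nh}"
        )
        truth_rows.append(
            {
                "query": qname,
                "cluster_id": c.cluster_id,
                "category": category,
                "valid": category == "valid",
                "failed": failed,
                "length_class": length_class,
            }
        )
    return "\n".join(lines) + "\n", pd.DataFrame(truth_rows)


SPAN_SHORT = (8, 21)
SPAN_LONG = (22, 72)


# ---------------------------------------------------------------------------
# NB count matrices with planted fold changes


@dataclass
class SynthCounts:
    matrix: "object"                  # diffexp.CountMatrix
    truth: pd.DataFrame               # feature, contrast, lfc, sign, motif
    isoacceptor_map: dict
    motif_features: tuple
    transitions: tuple


def synth_counts(cfg: SimConfig, features: Sequence[str] | None = None) -> SynthCounts:
    """NB count matrix over stages x replicates with planted log2 fold
    changes, including the opposite-sign-isodecoder construction: two
    members of one isoacceptor go up while the third goes down with exactly
    balancing magnitude, so the group sum is unchanged."""
    from .diffexp import CountMatrix

    rng = _rng(cfg, "counts")
    stages = cfg.stages
    transitions = tuple(f"{a}->{b}" for a, b in zip(stages, stages[1:]))
    if features is None:
        features = [f"cluster{i + 1}" for i in range(cfg.n_features)]
    features = list(features)
    iso_map = {f: f"iso{i // 3 + 1}" for i, f in enumerate(features)}

    motif: tuple = ()
    base = rng.lognormal(np.log(cfg.base_mean), 0.6, size=len(features))
    lfc = np.zeros((len(features), len(transitions)))
    truth_rows = []
    if cfg.masking_motif and len(features) >= 3:
        motif = tuple(features[:3])
        for f in motif:
            iso_map[f] = "isoM"
        base[0] = base[1] = 100.0
        base[2] = 800.0
        lfc[0, 0] = lfc[1, 0] = 2.0   # 100 -> 400, twice
        lfc[2, 0] = -2.0              # 800 -> 200: group sum 1000 -> 1000
        for j, f in enumerate(motif):
            truth_rows.append(
                {"feature": f, "contrast": transitions[0], "lfc": lfc[j, 0],
                 "sign": int(np.sign(lfc[j, 0])), "motif": True}
            )
    plain = [i for i, f in enumerate(features) if f not in motif]
    n_de = int(round(cfg.de_fraction * len(plain)))
    for t in range(len(transitions)):
        chosen = rng.choice(plain, size=min(2 * n_de, len(plain)), replace=False)
        for j, i in enumerate(chosen):
            sign = 1 if j < len(chosen) // 2 else -1
            lfc[i, t] = sign * cfg.de_lfc
            truth_rows.append(
                {"feature": features[i], "contrast": transitions[t],
                 "lfc": lfc[i, t], "sign": sign, "motif": False}
            )
    means = np.empty((len(features), len(stages)))
    means[:, 0] = base
    for t in range(len(transitions)):
        means[:, t + 1] = means[:, t] * 2.0 ** lfc[:, t]

    cols = {}
    sample_stage = {}
    disp = max(cfg.nb_dispersion, 1e-8)
    r = 1.0 / disp
    for s_idx, stage in enumerate(stages):
        for rep in range(cfg.n_replicates):
            name = f"{stage}_{rep + 1}"
            libscale = rng.uniform(0.7, 1.4)
            mu = means[:, s_idx] * libscale
            cols[name] = rng.negative_binomial(r, r / (r + mu))
            sample_stage[name] = stage
    counts = pd.DataFrame(cols, index=features)
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "contrast", "lfc", "sign", "motif"]
    )
    return SynthCounts(
        matrix=CountMatrix(counts=counts, sample_stage=sample_stage, level="cluster"),
        truth=truth,
        isoacceptor_map=iso_map,
        motif_features=motif,
        transitions=transitions,
    )
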
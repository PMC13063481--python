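"""Repertoire parsing, mature extraction, clustering and the localization test."""

import math
from dataclasses import replace

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import hypergeom

from trnakit.repertoire import (
    EnrichmentResult,
    TrnaGene,
    chrom_isotype_test,
    cluster_isodecoders,
    extract_mature,
    holm_adjust,
    parse_trnascan,
    summarize_repertoire,
)


def bio_revcomp(seq):
    """Independent reverse-complement oracle (Biopython route)."""
    return str(Seq(seq).reverse_complement())


class TestParseTrnascan:
    def test_fixture_roundtrip(self, trnascan_text):
        genes = parse_trnascan(trnascan_text.splitlines())
        assert len(genes) == 5
        by_id = {g.gene_id: g for g in genes}
        g1 = by_id["chr1.trna1"]
        assert (g1.start, g1.end, g1.strand) == (101, 172, "+")
        assert g1.isotype == "Ala" and g1.anticodon == "AGC"
        assert not g1.pseudogene and g1.introns == ()

    def test_minus_strand_normalized(self, trnascan_text):
        g = {x.gene_id: x for x in parse_trnascan(trnascan_text.splitlines())}["chr1.trna2"]
        assert (g.start, g.end, g.strand) == (229, 300, "-")

    def test_intron_and_pseudo_flags(self, trnascan_text):
        genes = {x.gene_id: x for x in parse_trnascan(trnascan_text.splitlines())}
        assert genes["chr2.trna1"].introns == ((80, 91),)
        assert genes["chr2.trna2"].pseudogene
        assert sum(g.pseudogene for g in genes.values()) == 2

    def test_undetermined_anticodon(self, trnascan_text):
        genes = {x.gene_id: x for x in parse_trnascan(trnascan_text.splitlines())}
        assert genes["chr2.trna3"].anticodon == "unknown"
        assert not genes["chr2.trna3"].has_anticodon

    def test_malformed_row_names_line(self):
        lines = ["chr1\t1\tnotanumber\t172\tAla\tAGC\t0\t0\t55.3"]
        with pytest.raises(ValueError, match="line 1"):
            parse_trnascan(lines)

    def test_unknown_isotype_warned_but_kept(self, caplog):
        lines = ["chr1\t1\t100\t170\tXyz\tAGC\t0\t0\t10.0"]
        with caplog.at_level("WARNING"):
            genes = parse_trnascan(lines)
        assert len(genes) == 1
        assert "Xyz" in caplog.text


class TestExtractMature:
    def test_plus_strand_substring(self, tiny_genome, tiny_genes, tiny_mature):
        g = tiny_genes[0]
        assert extract_mature(g, tiny_genome) == tiny_mature[g.gene_id]
        assert extract_mature(g, tiny_genome) == tiny_genome["chrA"][g.start - 1 : g.end]

    def test_minus_strand_revcomp(self, tiny_genome, tiny_genes, tiny_mature):
        g = tiny_genes[1]
        got = extract_mature(g, tiny_genome)
        assert got == tiny_mature[g.gene_id]
        assert got == bio_revcomp(tiny_genome["chrA"][g.start - 1 : g.end])

    def test_intron_removed(self, tiny_genome, tiny_genes, tiny_mature):
        g = tiny_genes[2]
        got = extract_mature(g, tiny_genome)
        assert got == tiny_mature[g.gene_id]
        assert len(got) == g.length - 12

    def test_strand_involution(self, tiny_genome, tiny_genes):
        for g in tiny_genes:
            flipped = replace(g, strand="-" if g.strand == "+" else "+")
            assert extract_mature(flipped, tiny_genome) == bio_revcomp(
                extract_mature(g, tiny_genome)
            )

    def test_out_of_bounds_rejected(self, tiny_genome):
        g = TrnaGene("x", "chrA", 100, 10_000, "+", "Ala", "AGC")
        with pytest.raises(ValueError, match="outside"):
            extract_mature(g, tiny_genome)
        with pytest.raises(ValueError, match="not in genome"):
            extract_mature(replace(g, chrom="chrZ"), tiny_genome)


class TestClusterIsodecoders:
    def _genome_with_copies(self):
        insert = "ACGT" * 18  # 72 nt mature
        other = "TTGG" * 18
        chrom = "C" * 15 + insert + "A" * 20 + insert + "T" * 20 + other + "G" * 15
        genes = [
            TrnaGene("c.trna1", "c", 16, 87, "+", "Ala", "AGC"),
            TrnaGene("c.trna2", "c", 108, 179, "+", "Ala", "AGC"),
            TrnaGene("c.trna3", "c", 200, 271, "+", "Gly", "GCC"),
        ]
        return {"c": chrom}, genes, insert, other

    def test_identical_sequences_one_cluster(self):
        genome, genes, insert, _ = self._genome_with_copies()
        clusters = cluster_isodecoders(genes[:2], genome)
        assert len(clusters) == 1
        assert clusters[0].members == ("c.trna1", "c.trna2")
        assert clusters[0].mature_seq == insert

    def test_three_genes_two_clusters(self):
        genome, genes, _, _ = self._genome_with_copies()
        clusters = cluster_isodecoders(genes, genome)
        assert sorted(len(c.members) for c in clusters) == [1, 2]

    def test_reference_structure(self):
        genome, genes, insert, _ = self._genome_with_copies()
        c = cluster_isodecoders(genes[:2], genome)[0]
        assert c.representative == "c.trna1"  # lexicographically smallest
        assert c.reference_seq == genome["c"][5:15] + insert + "CCA"
        assert c.reference_seq.endswith("CCA")
        assert len(c.reference_seq) == 10 + len(insert) + 3

    def test_minus_strand_flank_is_downstream_revcomp(self, tiny_genome, tiny_genes):
        clusters = cluster_isodecoders([tiny_genes[1]], tiny_genome)
        g = tiny_genes[1]
        expected_flank = bio_revcomp(tiny_genome["chrA"][g.end : g.end + 10])
        assert clusters[0].reference_seq[:10] == expected_flank

    def test_flank_padded_at_contig_edge(self, caplog):
        genome = {"c": "ACGT" * 18 + "AAAA"}
        genes = [TrnaGene("c.trna1", "c", 1, 72, "+", "Ala", "AGC")]
        with caplog.at_level("WARNING"):
            c = cluster_isodecoders(genes, genome)[0]
        assert c.reference_seq[:10] == "N" * 10
        assert "padded" in caplog.text

    def test_partition_invariant(self):
        from trnakit.synthetic_data import SimConfig, synth_genome

        sim = synth_genome(SimConfig(seed=3, n_genes=80, n_chroms=3))
        clusters = cluster_isodecoders(sim.genes, sim.genome)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(g.gene_id for g in sim.genes)
        assert len(clusters) == sim.truth["seq_label"].nunique()


class TestSummarize:
    def test_empty(self):
        s = summarize_repertoire([])
        assert s.counts == (0, None, 0, 0)

    def test_fixture_counts(self, tiny_genome):
        # 6 genes / 4 sequences / 3 anticodons / 2 isotypes
        seq_a, seq_b = "ACGT" * 18, "GGCC" * 18
        seq_c, seq_d = "ATAT" * 18, "CGCG" * 18
        chrom = "".join(
            "A" * 10 + s for s in (seq_a, seq_a, seq_b, seq_c, seq_d, seq_d)
        )
        genome = {"c": chrom}
        specs = [
            ("Ala", "AGC"), ("Ala", "AGC"), ("Ala", "AGC"),
            ("Ala", "TGC"), ("Gly", "GCC"), ("Gly", "GCC"),
        ]
        genes = []
        pos = 1
        for i, (iso, anti) in enumerate(specs):
            start = pos + 10
            genes.append(TrnaGene(f"c.trna{i}", "c", start, start + 71, "+", iso, anti))
            pos = start + 72
        clusters = cluster_isodecoders(genes, genome)
        s = summarize_repertoire(genes, clusters)
        assert s.counts == (6, 4, 3, 2)

    def test_hierarchy_inequalities(self):
        from trnakit.synthetic_data import SimConfig, synth_genome

        sim = synth_genome(SimConfig(seed=11, n_genes=100, n_chroms=2))
        clusters = cluster_isodecoders(sim.genes, sim.genome)
        s = summarize_repertoire(sim.genes, clusters)
        assert s.n_genes >= s.n_isodecoders >= s.n_isoacceptors >= s.n_isotypes

    def test_undetermined_excluded_from_class_tallies(self):
        genes = [
            TrnaGene("c.trna1", "c", 1, 70, "+", "Ala", "AGC"),
            TrnaGene("c.trna2", "c", 100, 170, "+", "Undet", "unknown"),
        ]
        s = summarize_repertoire(genes)
        assert s.n_genes == 2
        assert s.n_isoacceptors == 1
        assert s.n_isotypes == 1

    def test_density(self):
        genes = [TrnaGene("c1.trna1", "c1", 1, 70, "+", "Ala", "AGC")]
        s = summarize_repertoire(genes, chrom_sizes={"c1": 500_000, "c2": 1_000_000})
        assert s.gene_density["c1"] == pytest.approx(2.0)
        assert s.gene_density["c2"] == 0.0


def _two_chrom_genes(n1_ala, n1_gly, n2_ala, n2_gly):
    genes = []
    i = 0
    for chrom, iso, n in (
        ("chr1", "Ala", n1_ala), ("chr1", "Gly", n1_gly),
        ("chr2", "Ala", n2_ala), ("chr2", "Gly", n2_gly),
    ):
        for _ in range(n):
            i += 1
            genes.append(TrnaGene(f"{chrom}.trna{i}", chrom, i * 100, i * 100 + 70, "+", iso, "AGC"))
    return genes


class TestChromIsotypeTest:
    def test_single_isotype_degenerate(self):
        genes = _two_chrom_genes(3, 0, 2, 0)
        results = chrom_isotype_test(genes, n_draws=99, seed=1)
        assert all(r.p_value == 1.0 and r.degenerate for r in results)

    def test_deterministic(self):
        genes = _two_chrom_genes(5, 2, 1, 6)
        a = chrom_isotype_test(genes, n_draws=500, seed=42)
        b = chrom_isotype_test(genes, n_draws=500, seed=42)
        assert [r.p_value for r in a] == [r.p_value for r in b]
        c = chrom_isotype_test(genes, n_draws=500, seed=43)
        assert a != c or [r.p_value for r in a] == [r.p_value for r in c]

    def test_requires_two_chromosomes(self):
        genes = [TrnaGene("c.trna1", "c", 1, 70, "+", "Ala", "AGC")] * 2
        with pytest.raises(ValueError, match="chromosome"):
            chrom_isotype_test(genes, n_draws=10, seed=0)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            chrom_isotype_test(_two_chrom_genes(1, 1, 1, 1), n_draws=10)

    def test_monte_carlo_matches_enumeration_2x2(self):
        # chr1: all 3 Ala of pool (3 Ala, 3 Gly); statistic = pmf of the
        # Ala count k ~ Hypergeom(N=6, K=3, n=3); exact p = P(pmf <= pmf(3))
        genes = _two_chrom_genes(3, 0, 0, 3)
        n_draws = 20_000
        res = chrom_isotype_test(genes, n_draws=n_draws, seed=7)[0]
        pmf = {k: hypergeom.pmf(k, 6, 3, 3) for k in range(4)}
        obs = pmf[3]
        exact = sum(p for p in pmf.values() if p <= obs + 1e-12)
        se = math.sqrt(exact * (1 - exact) / n_draws)
        assert 0 < exact < 1
        assert abs(res.p_value - exact) <= 3 * se + 1 / n_draws

    def test_observed_sums_to_chromosome_count(self):
        genes = _two_chrom_genes(4, 3, 2, 5)
        for r in chrom_isotype_test(genes, n_draws=50, seed=0):
            n_c = sum(1 for g in genes if g.chrom == r.chrom)
            assert sum(r.observed) == n_c


class TestHolm:
    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_single_p_identity(self):
        assert holm_adjust([0.031])[0] == pytest.approx(0.031)
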
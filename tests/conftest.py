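"""Shared fixtures: the standard code, the full decoding graph, and small
hand-built genome/gene fixtures with independently computed expectations."""

import pytest

from trnakit.genetic_code import STANDARD_CODE
from trnakit.repertoire import TrnaGene
from trnakit.wobble_graph import build_graph


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def full_graph(code):
    """Graph with every anticodon flagged existing."""
    return build_graph(code, code.sense_anticodons)


@pytest.fixture(scope="session")
def bare_graph(code):
    """Graph with an empty repertoire (all vertices missing)."""
    return build_graph(code)


# hand-built two-chromosome genome.  Gene sequences are short strings chosen
# so expected mature sequences can be written down directly.
_GENE1 = "GGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAA"  # 69 nt
_GENE2 = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"  # 71 nt
_EXON1 = "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTT"  # 36 nt
_INTRON = "GAGAGAGAGAGA"  # 12 nt
_EXON2 = "CCCCGGGGAAAATTTTCCCCGGGGAAAATTTTCCC"  # 35 nt


@pytest.fixture(scope="session")
def tiny_genome():
    # chrA: 10 nt pad, gene1 (+), 10 nt pad, gene2 placed as minus strand
    # chrB: 20 nt pad, intron-bearing gene (+)
    from trnakit.genetic_code import revcomp

    chra = "A" * 10 + _GENE1 + "C" * 10 + revcomp(_GENE2) + "G" * 10
    chrb = "T" * 20 + _EXON1 + _INTRON + _EXON2 + "A" * 15
    return {"chrA": chra, "chrB": chrb}


@pytest.fixture(scope="session")
def tiny_genes():
    g1 = TrnaGene("chrA.trna1", "chrA", 11, 79, "+", "Gly", "GCC")
    # gene2 occupies chrA[90..159] 1-based (70 nt); coding strand is minus
    g2 = TrnaGene("chrA.trna2", "chrA", 90, 159, "-", "Ala", "AGC")
    # intron gene: chrB[21..103], intron at chrB[57..68] (12 nt)
    g3 = TrnaGene("chrB.trna1", "chrB", 21, 103, "+", "Leu", "CAA", introns=((57, 68),))
    return [g1, g2, g3]


@pytest.fixture(scope="session")
def tiny_mature():
    """Independently written-down mature sequences for tiny_genes."""
    return {
        "chrA.trna1": _GENE1,
        "chrA.trna2": _GENE2,
        "chrB.trna1": _EXON1 + _EXON2,
    }


TRNASCAN_FIXTURE = """\
Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\t
Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote
--------\t------\t-----\t----\t----\t-----\t-----\t----\t------\t------
chr1\t1\t101\t172\tAla\tAGC\t0\t0\t55.3\t
chr1\t2\t300\t229\tGly\tGCC\t0\t0\t60.1\t
chr2\t1\t50\t131\tLeu\tCAA\t80\t91\t47.2\t
chr2\t2\t500\t571\tSer\tTGA\t0\t0\t32.0\tpseudo
chr2\t3\t700\t771\tUndet\tNNN\t0\t0\t30.0\tpseudo
"""


@pytest.fixture()
def trnascan_text():
    return TRNASCAN_FIXTURE
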
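"""Genetic-code tables and codon/anticodon algebra.

Codons and anticodons are plain DNA strings written 5'->3'.  An anticodon's
first character is its wobble position (tRNA position 34), which pairs the
third position of its cognate codon; the cognate codon of an anticodon is
its reverse complement.  Inosine is represented by its genomically encoded
A at the wobble position -- no separate symbol is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Data import CodonTable, IUPACData

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = ("A", "C", "G", "T")

#: one-letter -> three-letter amino-acid symbols (isotype labels)
AA_1TO3: dict[str, str] = {
    aa1: aa3 for aa1, aa3 in IUPACData.protein_letters_1to3.items()
}
AA_3TO1: dict[str, str] = {v: k for k, v in AA_1TO3.items()}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return len(seq) > 0 and all(b in "ACGT" for b in seq)


def anticodon_of(codon: str) -> str:
    """Anticodon (5'->3') pairing the given codon."""
    return revcomp(codon)


def codon_of(anticodon: str) -> str:
    """Cognate codon (5'->3') of the given anticodon."""
    return revcomp(anticodon)


def wobble_base(anticodon: str) -> str:
    """Base at tRNA position 34 -- the first character of the anticodon."""
    return anticodon[0]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code over DNA codons.

    Parameters
    ----------
    table:
        Map from the 61 sense codons to one-letter amino-acid symbols.
    stop_codons:
        The stop triplets.  Under the default policy TGA is a stop
        (selenocysteine is excluded from all analyses built on this code).
    """

    table: Mapping[str, str]
    stop_codons: frozenset

    def __post_init__(self) -> None:
        if len(self.table) != 64 - len(self.stop_codons):
            raise ValueError(
                f"expected {64 - len(self.stop_codons)} sense codons, "
                f"got {len(self.table)}"
            )
        overlap = set(self.table) & set(self.stop_codons)
        if overlap:
            raise ValueError(f"codons both sense and stop: {sorted(overlap)}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard code; stops are {TAA, TAG, TGA}."""
        tbl = CodonTable.unambiguous_dna_by_id[1]
        return cls(
            table=dict(tbl.forward_table),
            stop_codons=frozenset(tbl.stop_codons),
        )

    @property
    def sense_codons(self) -> frozenset:
        return frozenset(self.table)

    @property
    def sense_anticodons(self) -> frozenset:
        return frozenset(revcomp(c) for c in self.table)

    def aa(self, codon: str) -> str:
        """One-letter amino acid encoded by a sense codon."""
        return self.table[codon]

    def anticodon_aa(self, anticodon: str) -> str:
        """Amino acid carried by the tRNA with this anticodon."""
        return self.table[codon_of(anticodon)]

    def anticodon_isotype(self, anticodon: str) -> str:
        """Three-letter isotype label of the anticodon's amino acid."""
        return AA_1TO3[self.anticodon_aa(anticodon)]

    def is_sense_codon(self, codon: str) -> bool:
        return codon in self.table

    def is_sense_anticodon(self, anticodon: str) -> bool:
        return is_dna(anticodon) and len(anticodon) == 3 and codon_of(anticodon) in self.table

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


STANDARD_CODE = GeneticCode.standard()
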
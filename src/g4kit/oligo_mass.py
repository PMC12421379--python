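"""Theoretical oligonucleotide molecular weights (average isotopic).

Used to assign oligomeric state against SEC-MALS measurements: the measured
solution mass is compared with ``copies x`` the single-strand theoretical
mass.  Masses follow the standard vendor convention for linear oligos with
5'-OH termini: the sum of internal (monophosphate) residue masses minus a
constant 61.96 Da per strand; a 5'-phosphate adds 79.98 Da.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = ["OligoSpec", "molecular_weight", "count_bases", "read_fasta_sequence"]

# average residue masses, Da (internal residues of a linear chain)
DNA_RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
RNA_RESIDUE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}

FIVE_PRIME_OH_CONSTANT = 61.96  # subtracted once per strand
FIVE_PRIME_PHOSPHATE = 79.98  # added per strand for 5'-phosphate termini


@dataclass
class OligoSpec:
    sequence: str
    nucleic_type: str = "dna"  # dna | rna
    five_prime: str = "OH"  # OH | phosphate
    copies: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip().upper()
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.nucleic_type not in ("dna", "rna"):
            raise ValueError(f"nucleic_type must be dna or rna, got {self.nucleic_type!r}")
        if self.five_prime not in ("OH", "phosphate"):
            raise ValueError(f"five_prime must be OH or phosphate, got {self.five_prime!r}")
        if self.copies < 1:
            raise ValueError("copies must be a positive integer")
        table = DNA_RESIDUE_MASS if self.nucleic_type == "dna" else RNA_RESIDUE_MASS
        for i, ch in enumerate(self.sequence):
            if ch not in table:
                raise ValueError(
                    f"invalid {self.nucleic_type.upper()} base {ch!r} at position {i + 1}"
                )


def molecular_weight(spec: OligoSpec) -> tuple[float, float]:
    """Average molecular weight of the oligomer.

    Returns ``(mass_da, mass_kda)`` with the kDa value rounded to one
    decimal.  Per strand: sum of residue masses minus 61.96 Da (5'-OH), or
    plus 79.98 Da for a 5'-phosphate.
    """
    table = DNA_RESIDUE_MASS if spec.nucleic_type == "dna" else RNA_RESIDUE_MASS
    strand = sum(table[ch] for ch in spec.sequence) - FIVE_PRIME_OH_CONSTANT
    if spec.five_prime == "phosphate":
        strand += FIVE_PRIME_PHOSPHATE
    total = spec.copies * strand
    return total, round(total / 1000.0, 1)


def count_bases(sequence: str) -> dict[str, int]:
    """Exact per-base counts over A/C/G/T/U (other characters rejected)."""
    seq = sequence.strip().upper()
    counts = {b: 0 for b in "ACGTU"}
    for i, ch in enumerate(seq):
        if ch not in counts:
            raise ValueError(f"invalid base {ch!r} at position {i + 1}")
        counts[ch] += 1
    return counts


def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file as an uppercase string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
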
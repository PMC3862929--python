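"""Genetic-code tables shared across the package.

Everything is expressed in DNA alphabet (T, not U); the four "UCN" serine
codons of the mRNA are therefore written TCA/TCC/TCG/TCT throughout.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: The 61 sense codons of the standard genetic code, sorted.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))

#: amino acid (one-letter) -> sorted tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, [])
    SYNONYMOUS_FAMILIES[_aa].append(_codon)
SYNONYMOUS_FAMILIES = {aa: tuple(sorted(cs)) for aa, cs in SYNONYMOUS_FAMILIES.items()}

#: codon -> amino acid for sense codons
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

SERINE_CODONS: tuple[str, ...] = SYNONYMOUS_FAMILIES["S"]  # AGC AGT TCA TCC TCG TCT
TCN_CODONS: tuple[str, ...] = ("TCA", "TCC", "TCG", "TCT")
AGY_CODONS: tuple[str, ...] = ("AGC", "AGT")
CYSTEINE_CODONS: tuple[str, ...] = SYNONYMOUS_FAMILIES["C"]  # TGC TGT

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iter_codons(cds: str):
    """Yield successive frame-0 codons of ``cds`` (length must be a multiple of 3)."""
    for i in range(0, len(cds), 3):
        yield cds[i : i + 3]
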
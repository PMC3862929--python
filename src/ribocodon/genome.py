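"""Genome and annotation data model.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
reader converts from the 1-based inclusive file convention at the boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from .codons import revcomp

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass
class Genome:
    """A set of contig sequences over the strict A/C/G/T alphabet."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                pos = next(i for i, b in enumerate(seq) if b not in _VALID_BASES)
                raise ValueError(
                    f"contig {name!r} contains non-ACGT character "
                    f"{seq[pos]!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class Gene:
    """A strand-aware CDS interval on a contig.

    ``start``/``end`` are 0-based half-open nucleotide coordinates; the CDS
    must consist of a start codon, at least one sense codon and a stop codon
    (length divisible by 3 and >= 9 nt).
    """

    id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        length = self.end - self.start
        if length < 9 or length % 3 != 0:
            raise ValueError(
                f"gene {self.id}: CDS length {length} must be >= 9 and divisible by 3"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        """Total codon count including the start and stop codons."""
        return self.length_nt // 3


def read_genome(path: str | os.PathLike) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Sequences are uppercased; an empty file or any non-ACGT character is an
    error (the error names the offending record and 1-based position).
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(contigs)


def _gene_id_from_attributes(feature, index: int) -> str:
    for key in ("ID", "locus_tag", "gene", "Name", "Parent"):
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return f"cds_{index}"


def read_annotation(path: str | os.PathLike, genome: Genome) -> list[Gene]:
    """Read CDS features from a GFF3 file as a list of :class:`Gene`.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    CDS features whose length is not a positive multiple of 3 (minimum 9 nt)
    are skipped with a logged warning; a CDS extending past its contig is an
    error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[Gene] = []
    n_skipped = 0
    for index, feature in enumerate(db.features_of_type("CDS")):
        start = feature.start - 1
        end = feature.end
        gene_id = _gene_id_from_attributes(feature, index)
        if feature.seqid not in genome.contigs:
            raise ValueError(f"CDS {gene_id}: unknown contig {feature.seqid!r}")
        if start < 0 or end > len(genome.contigs[feature.seqid]):
            raise ValueError(
                f"CDS {gene_id}: interval [{start}, {end}) outside contig {feature.seqid!r}"
            )
        length = end - start
        if length < 9 or length % 3 != 0:
            logger.warning(
                "skipping CDS %s: length %d not a multiple of 3 (>= 9 nt)", gene_id, length
            )
            n_skipped += 1
            continue
        product = (feature.attributes.get("product") or [""])[0]
        genes.append(
            Gene(
                id=gene_id,
                contig=feature.seqid,
                start=start,
                end=end,
                strand=feature.strand,
                product=product,
            )
        )
    if not genes:
        logger.warning("no usable CDS features found in %s (%d skipped)", path, n_skipped)
    return genes


def extract_cds(genome: Genome, gene: Gene) -> str:
    """Return the CDS nucleotide sequence in transcript orientation.

    For minus-strand genes the genomic slice is reverse-complemented, so the
    returned string always starts with the start codon.
    """
    contig_seq = genome.contigs.get(gene.contig)
    if contig_seq is None:
        raise ValueError(f"gene {gene.id}: unknown contig {gene.contig!r}")
    if gene.start < 0 or gene.end > len(contig_seq):
        raise ValueError(
            f"gene {gene.id}: interval [{gene.start}, {gene.end}) outside contig"
        )
    seq = contig_seq[gene.start : gene.end]
    return revcomp(seq) if gene.strand == "-" else seq
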
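"""Footprint read processing: trimming, ncRNA filtering, alignment ingestion
and A-site density assignment.

The density convention follows the center-weighting scheme used for
bacterial ribosome profiling: each ungapped alignment of length L is trimmed
by ``end_trim`` (default 8) nucleotides from each end to approximate the
ribosome A-site region, and the remaining span contributes 1/(L - 2*end_trim)
read-equivalents to each of its positions on the alignment's strand.  Total
track mass therefore equals the number of contributing alignments.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pysam

from .codons import revcomp
from .genome import Gene, Genome

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality length mismatch")


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    contig: str
    start: int  # 0-based leftmost genomic coordinate
    length: int
    strand: str
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"alignment {self.read_id}: length must be >= 1")
        if self.strand not in STRANDS:
            raise ValueError(f"alignment {self.read_id}: bad strand {self.strand!r}")


def discard_first_base(read: Read) -> Read | None:
    """Drop the ambiguous first 5' nucleotide of a library read."""
    if len(read.sequence) <= 1:
        return None
    return Read(
        read.id,
        read.sequence[1:],
        read.quality[1:] if read.quality is not None else None,
    )


def trim_polya(read: Read, min_polya: int = 10) -> Read | None:
    """Remove the polyA library tail.

    If a run of at least ``min_polya`` consecutive adenines exists, every
    nucleotide from one position before the start of the run onward is
    discarded (the base adjacent to the run cannot be distinguished from a
    genuine templated A, so it is sacrificed).  Returns ``None`` when nothing
    is left.
    """
    match = re.search("A{%d,}" % min_polya, read.sequence)
    if match is None:
        return read
    cut = max(match.start() - 1, 0)
    if cut == 0:
        return None
    return Read(
        read.id,
        read.sequence[:cut],
        read.quality[:cut] if read.quality is not None else None,
    )


def trim_read(read: Read, min_polya: int = 10, min_keep: int = 17) -> Read | None:
    """Full library trim: drop the 5' base, remove the polyA tail, and mark
    reads shorter than ``min_keep`` as discarded (returned as ``None``).

    ``min_keep`` defaults to 17 nt, the shortest alignment for which the
    8-nt end trim still leaves one density position.
    """
    trimmed = discard_first_base(read)
    if trimmed is not None:
        trimmed = trim_polya(trimmed, min_polya=min_polya)
    if trimmed is None or len(trimmed.sequence) < min_keep:
        return None
    return trimmed


def trim_reads(
    reads: list[Read], min_polya: int = 10, min_keep: int = 17
) -> tuple[list[Read], int]:
    """Trim a batch of reads; returns (kept reads, number discarded)."""
    kept: list[Read] = []
    n_discarded = 0
    for read in reads:
        trimmed = trim_read(read, min_polya=min_polya, min_keep=min_keep)
        if trimmed is None:
            n_discarded += 1
        else:
            kept.append(trimmed)
    return kept, n_discarded


def filter_ncrna(reads: list[Read], ncrna: Genome) -> list[Read]:
    """Drop reads matching a non-coding RNA record on either strand.

    A read is removed when its sequence or reverse complement occurs as an
    exact substring of any ncRNA sequence; survivors keep their input order.
    """
    sequences = list(ncrna.contigs.values())
    kept: list[Read] = []
    n_removed = 0
    for read in reads:
        rc = revcomp(read.sequence)
        if any(read.sequence in s or rc in s for s in sequences):
            n_removed += 1
        else:
            kept.append(read)
    if n_removed:
        logger.info("filter_ncrna removed %d of %d reads", n_removed, len(reads))
    return kept


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    pos = haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def align_exact(reads: list[Read], genome: Genome) -> list[AlignedRead]:
    """Exact-match, unique-hit alignment of mismatch-free reads.

    Both strands of every contig are searched for the read sequence as an
    exact substring; reads with exactly one genomic occurrence produce one
    :class:`AlignedRead` (start = leftmost genomic coordinate on either
    strand), reads with zero or multiple occurrences are dropped.
    """
    aligned: list[AlignedRead] = []
    n_unaligned = 0
    n_multi = 0
    cache: dict[str, list[tuple[str, int, str]]] = {}
    for read in reads:
        hits = cache.get(read.sequence)
        if hits is None:
            hits = []
            rc = revcomp(read.sequence)
            for contig, seq in genome.contigs.items():
                hits.extend((contig, p, "+") for p in _find_all(seq, read.sequence))
                hits.extend((contig, p, "-") for p in _find_all(seq, rc))
            cache[read.sequence] = hits
        if len(hits) == 1:
            contig, pos, strand = hits[0]
            aligned.append(
                AlignedRead(read.id, contig, pos, len(read.sequence), strand, mismatches=0)
            )
        elif not hits:
            n_unaligned += 1
        else:
            n_multi += 1
    if n_unaligned or n_multi:
        logger.info(
            "align_exact: %d aligned, %d unaligned, %d multi-mapping dropped",
            len(aligned), n_unaligned, n_multi,
        )
    return aligned


def _ensure_sam_header(path: str) -> str:
    """Return a SAM path guaranteed to carry @SQ lines, synthesizing a header
    from the records when the input lacks one (pysam cannot iterate a
    headerless SAM)."""
    with open(path) as fh:
        lines = fh.readlines()
    if any(line.startswith("@SQ") for line in lines):
        return path
    contigs: dict[str, int] = {}
    for line in lines:
        if line.startswith("@") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11 or fields[2] == "*":
            continue
        end = int(fields[3]) + len(fields[9])
        contigs[fields[2]] = max(contigs.get(fields[2], 0), end + 1)
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", delete=False, prefix="ribocodon_"
    )
    with tmp as out:
        for name, ln in contigs.items():
            out.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        out.writelines(line for line in lines if not line.startswith("@"))
    return tmp.name


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read a SAM file (ungapped alignments only) into AlignedRead records.

    Unmapped records are skipped silently; records whose CIGAR contains
    anything other than M operations (indels, clipping) are skipped with a
    warning.  Mismatch counts come from the NM tag (0 when absent).
    """
    sam_path = _ensure_sam_header(str(path))
    alignments: list[AlignedRead] = []
    n_skipped_cigar = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples or []
            if any(op != 0 for op, _ in cig):
                logger.warning(
                    "skipping %s: unsupported CIGAR %s", rec.query_name, rec.cigarstring
                )
                n_skipped_cigar += 1
                continue
            length = sum(n for _, n in cig) if cig else len(rec.query_sequence or "")
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alignments.append(
                AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    length=length,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(nm),
                )
            )
    if sam_path != str(path):
        os.unlink(sam_path)
    return alignments


def filter_alignments(
    alignments: list[AlignedRead], max_mismatches: int = 2
) -> list[AlignedRead]:
    """Keep alignments with at most ``max_mismatches`` mismatches."""
    return [a for a in alignments if a.mismatches <= max_mismatches]


@dataclass
class DensityTrack:
    """Per-nucleotide, per-strand read density (read-equivalents per nt)."""

    data: dict[str, dict[str, np.ndarray]]
    n_reads_assigned: float = 0
    n_skipped_short: int = 0

    @classmethod
    def zeros(cls, genome: Genome) -> "DensityTrack":
        data = {
            contig: {s: np.zeros(len(seq)) for s in STRANDS}
            for contig, seq in genome.contigs.items()
        }
        return cls(data)

    def total_mass(self) -> float:
        return float(
            sum(arr.sum() for per_strand in self.data.values() for arr in per_strand.values())
        )

    def gene_profile(self, gene: Gene) -> np.ndarray:
        """Per-nucleotide density over a gene in transcript orientation."""
        arr = self.data[gene.contig][gene.strand][gene.start : gene.end]
        return arr[::-1].copy() if gene.strand == "-" else arr.copy()

    def scaled(self, factor: float) -> "DensityTrack":
        data = {
            c: {s: arr * factor for s, arr in per_strand.items()}
            for c, per_strand in self.data.items()
        }
        return DensityTrack(data, self.n_reads_assigned, self.n_skipped_short)

    def __add__(self, other: "DensityTrack") -> "DensityTrack":
        data = {
            c: {s: self.data[c][s] + other.data[c][s] for s in self.data[c]}
            for c in self.data
        }
        return DensityTrack(
            data,
            self.n_reads_assigned + other.n_reads_assigned,
            self.n_skipped_short + other.n_skipped_short,
        )


def build_density_track(
    alignments: list[AlignedRead], genome: Genome, end_trim: int = 8
) -> DensityTrack:
    """Accumulate A-site-proximal density from ungapped alignments.

    Each alignment of length L with L - 2*end_trim >= 1 adds
    1/(L - 2*end_trim) to every position of its end-trimmed span on its own
    strand; shorter alignments are skipped and counted.
    """
    track = DensityTrack.zeros(genome)
    # difference-array accumulation per contig/strand, then cumulative sum
    buckets: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    n_assigned = 0
    n_short = 0
    for aln in alignments:
        m = aln.length - 2 * end_trim
        if m < 1:
            n_short += 1
            continue
        s = aln.start + end_trim
        buckets.setdefault((aln.contig, aln.strand), []).append((s, s + m, 1.0 / m))
        n_assigned += 1
    for (contig, strand), spans in buckets.items():
        n = len(track.data[contig][strand])
        diff = np.zeros(n + 1)
        starts = np.fromiter((s for s, _, _ in spans), dtype=np.int64, count=len(spans))
        ends = np.fromiter((e for _, e, _ in spans), dtype=np.int64, count=len(spans))
        weights = np.fromiter((w for _, _, w in spans), dtype=np.float64, count=len(spans))
        if starts.min() < 0 or ends.max() > n:
            raise ValueError(f"alignment span outside contig {contig!r}")
        np.add.at(diff, starts, weights)
        np.subtract.at(diff, ends, weights)
        track.data[contig][strand] = np.cumsum(diff[:-1])
    track.n_reads_assigned = n_assigned
    track.n_skipped_short = n_short
    return track


def write_bedgraph(track: DensityTrack, path_plus: str, path_minus: str) -> None:
    """Write one bedGraph file per strand (runs of equal value merged)."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as out:
            for contig, per_strand in sorted(track.data.items()):
                arr = per_strand[strand]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    if arr[s] != 0.0:
                        out.write(f"{contig}\t{s}\t{e}\t{arr[s]:.10g}\n")


def read_bedgraph(path_plus: str, path_minus: str, genome: Genome) -> DensityTrack:
    """Load a strand pair of bedGraph files produced by :func:`write_bedgraph`."""
    track = DensityTrack.zeros(genome)
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                contig, s, e, v = line.split("\t")
                track.data[contig][strand][int(s) : int(e)] = float(v)
    track.n_reads_assigned = track.total_mass()
    return track
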
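"""Per-gene read counting and median-subtracted log2 fold-changes.

Counting assigns each end-trimmed alignment to the unique same-strand gene
containing the midpoint of its trimmed span.  Fold-changes between two
samples are log2 count ratios with the median over qualifying genes (>= 100
reads in at least one sample, by default) subtracted, which removes global
library-size differences without any further normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .footprints import AlignedRead
from .genome import Gene, Genome

logger = logging.getLogger(__name__)


@dataclass
class GeneCounts:
    sample_id: str
    counts: dict[str, int]
    n_assigned: int
    n_ambiguous: int = 0


@dataclass
class FoldChangeRecord:
    gene_id: str
    count_a: int
    count_b: int
    log2fc_raw: float  # may be +-inf or nan when a count is zero
    log2fc_adj: float  # nan unless passes_min_reads and log2fc_raw finite
    passes_min_reads: bool


def gene_counts(
    alignments: list[AlignedRead],
    genes: list[Gene],
    genome: Genome,
    end_trim: int = 8,
    sample_id: str = "sample",
) -> GeneCounts:
    """Count alignments per gene by trimmed-span midpoint.

    An alignment is credited to the unique gene whose CDS interval on the
    matching strand contains the midpoint of its end-trimmed span; midpoints
    inside two overlapping same-strand genes are counted for neither.
    """
    # paint a gene-index map per contig/strand; -1 free, -2 ambiguous overlap
    index: dict[str, dict[str, np.ndarray]] = {
        contig: {s: np.full(len(seq), -1, dtype=np.int64) for s in ("+", "-")}
        for contig, seq in genome.contigs.items()
    }
    for gi, gene in enumerate(genes):
        arr = index[gene.contig][gene.strand]
        span = arr[gene.start : gene.end]
        span[span == -1] = gi
        overlap = (span >= 0) & (span != gi)
        span[overlap] = -2
        arr[gene.start : gene.end] = span
    counts = {g.id: 0 for g in genes}
    n_assigned = 0
    n_ambiguous = 0
    for aln in alignments:
        s = aln.start + end_trim
        e = aln.start + aln.length - end_trim
        if e - s < 1:
            continue
        mid = (s + e) // 2
        gi = index[aln.contig][aln.strand][mid]
        if gi >= 0:
            counts[genes[gi].id] += 1
            n_assigned += 1
        elif gi == -2:
            n_ambiguous += 1
    return GeneCounts(sample_id, counts, n_assigned, n_ambiguous)


def log2_fold_changes(
    a: GeneCounts,
    b: GeneCounts,
    min_reads: int = 100,
    pseudocount: float = 0.0,
) -> list[FoldChangeRecord]:
    """Median-subtracted log2 fold-changes (a over b) per gene.

    A gene qualifies when max(count_a, count_b) >= ``min_reads``.  With zero
    pseudocount a zero denominator (or numerator) yields a non-finite raw
    value that is excluded from the median and carries nan as its adjusted
    value.  The median of finite qualifying raw fold-changes is subtracted
    from each of them, so the adjusted values have median zero by
    construction.
    """
    shared = sorted(set(a.counts) & set(b.counts))
    if not shared:
        raise ValueError("no shared genes between samples")
    records: list[FoldChangeRecord] = []
    for gene_id in shared:
        ca, cb = a.counts[gene_id], b.counts[gene_id]
        num, den = ca + pseudocount, cb + pseudocount
        if num > 0 and den > 0:
            raw = math.log2(num / den)
        elif num > 0:
            raw = math.inf
        elif den > 0:
            raw = -math.inf
        else:
            raw = math.nan
        passes = max(ca, cb) >= min_reads
        records.append(FoldChangeRecord(gene_id, ca, cb, raw, math.nan, passes))
    qualifying = [
        r.log2fc_raw for r in records if r.passes_min_reads and math.isfinite(r.log2fc_raw)
    ]
    if not qualifying:
        raise ValueError(f"no genes pass the >= {min_reads}-read filter with finite ratios")
    med = float(np.median(qualifying))
    for r in records:
        if r.passes_min_reads and math.isfinite(r.log2fc_raw):
            r.log2fc_adj = r.log2fc_raw - med
    return records


def preferential_set(
    fc_1: list[FoldChangeRecord],
    fc_2: list[FoldChangeRecord],
    fold_threshold: float = 10.0,
) -> set[str]:
    """Genes induced at least ``fold_threshold``-fold more in comparison 1
    than in comparison 2 (difference of adjusted log2 fold-changes)."""
    by_id_2 = {r.gene_id: r for r in fc_2}
    cutoff = math.log2(fold_threshold)
    selected: set[str] = set()
    for r1 in fc_1:
        r2 = by_id_2.get(r1.gene_id)
        if r2 is None:
            continue
        if not (math.isfinite(r1.log2fc_adj) and math.isfinite(r2.log2fc_adj)):
            continue
        if r1.log2fc_adj - r2.log2fc_adj >= cutoff:
            selected.add(r1.gene_id)
    return selected


def r_squared(fc_1: list[FoldChangeRecord], fc_2: list[FoldChangeRecord]) -> float:
    """Squared Pearson correlation of adjusted log2 fold-changes across the
    shared qualifying genes of two comparisons."""
    by_id_2 = {r.gene_id: r for r in fc_2}
    xs, ys = [], []
    for r1 in fc_1:
        r2 = by_id_2.get(r1.gene_id)
        if r2 is None:
            continue
        if math.isfinite(r1.log2fc_adj) and math.isfinite(r2.log2fc_adj):
            xs.append(r1.log2fc_adj)
            ys.append(r2.log2fc_adj)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 shared finite records, got {len(xs)}")
    if np.std(xs) == 0.0 or np.std(ys) == 0.0:
        raise ValueError("zero variance in one of the fold-change sets")
    r, _ = pearsonr(xs, ys)
    return float(r * r)
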
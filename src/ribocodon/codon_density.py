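"""Per-codon ribosome/mRNA occupancy statistics.

The central quantity is the relative occupancy of a codon within a gene:
the density at the codon's first nucleotide (transcript orientation),
averaged over the codon's occurrences in that gene, divided by the gene's
average per-nucleotide density.  A codon with no over- or
under-representation of ribosomes therefore scores exactly 1.  Genome-wide,
each codon's per-gene values are summarized by their median across genes
with adequate coverage, and reported relative to the median over the 61
sense-codon medians.

The start codon is treated as a separate key ("START") irrespective of its
identity, and the terminal codon is reported under "STOP"; neither enters
the 61-codon summaries, but both contribute to each gene's average density,
which slightly deflates all other codons when start/stop occupancy is high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, iter_codons
from .footprints import DensityTrack
from .genome import Gene, Genome, extract_cds

START_KEY = "START"
STOP_KEY = "STOP"


@dataclass
class GeneDensitySummary:
    gene_id: str
    per_nt_avg: float
    per_codon_avg: float
    passes_coverage: bool


@dataclass
class CodonDensityTable:
    """Genome-wide per-codon occupancy summary.

    ``per_gene_values`` maps each key (61 sense codons plus START/STOP) to
    the per-gene relative occupancies of genes containing that codon;
    ``median_relative`` divides each codon's median by the median over the
    61 sense-codon medians.
    """

    per_gene_values: dict[str, np.ndarray]
    median: dict[str, float]
    median_relative: dict[str, float]
    n_genes: dict[str, int]
    n_genes_passing: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": key,
                "n_genes": self.n_genes[key],
                "median": self.median[key],
                "median_relative": self.median_relative.get(key, float("nan")),
            }
            for key in self.median
        ]
        return pd.DataFrame(rows).set_index("codon")


@dataclass
class MotifProfile:
    """Median normalized density around occurrences of one trinucleotide."""

    motif: str
    offsets: np.ndarray  # -flank .. flank-1 relative to motif start
    values: np.ndarray | None  # None when no occurrence was retained
    n_occurrences: int

    @property
    def is_empty(self) -> bool:
        return self.values is None


def gene_density(
    track: DensityTrack, gene: Gene, coverage_threshold: float = 1.0
) -> GeneDensitySummary:
    """Average per-nucleotide and per-codon density over a gene.

    The sum runs over the whole CDS including start and stop codons; the
    coverage criterion is >= ``coverage_threshold`` reads per codon.
    """
    profile = track.gene_profile(gene)
    per_nt = float(profile.sum()) / gene.length_nt
    per_codon = 3.0 * per_nt
    return GeneDensitySummary(gene.id, per_nt, per_codon, per_codon >= coverage_threshold)


def per_gene_codon_values(
    track: DensityTrack, gene: Gene, genome: Genome
) -> dict[str, float]:
    """Relative occupancy of each codon present in one gene.

    Returns a map from codon identity (plus START and STOP) to the density
    at the codon's first nucleotide, averaged over occurrences and divided
    by the gene's average per-nucleotide density.  Codons absent from the
    gene are absent from the map.
    """
    profile = track.gene_profile(gene)
    per_nt_avg = float(profile.mean())
    if per_nt_avg == 0.0:
        raise ValueError(f"gene {gene.id}: zero density, cannot normalize")
    codons = list(iter_codons(extract_cds(genome, gene)))
    first_nt = profile[:: 3]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    last = len(codons) - 1
    for i, codon in enumerate(codons):
        key = START_KEY if i == 0 else STOP_KEY if i == last else codon
        sums[key] = sums.get(key, 0.0) + float(first_nt[i])
        counts[key] = counts.get(key, 0) + 1
    return {key: sums[key] / counts[key] / per_nt_avg for key in sums}


def _collect_table(
    track: DensityTrack,
    genes: list[Gene],
    genome: Genome,
    coverage_threshold: float,
    codon_index_filter=None,
) -> CodonDensityTable:
    values: dict[str, list[float]] = {}
    n_passing = 0
    for gene in genes:
        summary = gene_density(track, gene, coverage_threshold)
        if not summary.passes_coverage:
            continue
        n_passing += 1
        if codon_index_filter is None:
            per_gene = per_gene_codon_values(track, gene, genome)
        else:
            per_gene = _filtered_codon_values(track, gene, genome, codon_index_filter)
        for key, v in per_gene.items():
            values.setdefault(key, []).append(v)
    if n_passing == 0:
        raise ValueError("no genes pass the coverage threshold")
    median = {key: float(np.median(vs)) for key, vs in values.items()}
    sense_medians = [median[c] for c in SENSE_CODONS if c in median]
    mom = float(np.median(sense_medians))
    if mom == 0.0:
        raise ValueError("median of sense-codon medians is zero")
    return CodonDensityTable(
        per_gene_values={k: np.asarray(v) for k, v in values.items()},
        median=median,
        median_relative={k: m / mom for k, m in median.items()},
        n_genes={k: len(v) for k, v in values.items()},
        n_genes_passing=n_passing,
    )


def _filtered_codon_values(
    track: DensityTrack, gene: Gene, genome: Genome, index_filter
) -> dict[str, float]:
    """Like per_gene_codon_values but restricted to codon indices accepted by
    ``index_filter(i, n_codons)``; normalization still uses the whole gene."""
    profile = track.gene_profile(gene)
    per_nt_avg = float(profile.mean())
    if per_nt_avg == 0.0:
        raise ValueError(f"gene {gene.id}: zero density, cannot normalize")
    codons = list(iter_codons(extract_cds(genome, gene)))
    first_nt = profile[::3]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    last = len(codons) - 1
    for i, codon in enumerate(codons):
        if not index_filter(i, len(codons)):
            continue
        key = START_KEY if i == 0 else STOP_KEY if i == last else codon
        sums[key] = sums.get(key, 0.0) + float(first_nt[i])
        counts[key] = counts.get(key, 0) + 1
    return {key: sums[key] / counts[key] / per_nt_avg for key in sums}


def genomewide_codon_density(
    track: DensityTrack,
    genes: list[Gene],
    genome: Genome,
    coverage_threshold: float = 1.0,
) -> CodonDensityTable:
    """Median per-codon occupancy across all genes passing the coverage filter."""
    return _collect_table(track, genes, genome, coverage_threshold)


def split_half_codon_density(
    track: DensityTrack,
    genes: list[Gene],
    genome: Genome,
    coverage_threshold: float = 1.0,
) -> tuple[CodonDensityTable, CodonDensityTable]:
    """Codon occupancy computed separately for each gene's two halves.

    Codons are partitioned by index: the first ceil(C/2) codons of a
    C-codon gene go to the first-half table, the rest to the second; the
    whole-gene average density is reused for normalization in both.
    """
    first = _collect_table(
        track, genes, genome, coverage_threshold,
        codon_index_filter=lambda i, n: i < math.ceil(n / 2),
    )
    second = _collect_table(
        track, genes, genome, coverage_threshold,
        codon_index_filter=lambda i, n: i >= math.ceil(n / 2),
    )
    return first, second


def sd_motif_profile(
    track: DensityTrack,
    genes: list[Gene],
    genome: Genome,
    motifs: list[str],
    flank: int = 30,
    coverage_threshold: float = 1.0,
) -> list[MotifProfile]:
    """Metagene density around trinucleotide motifs (Shine-Dalgarno-like).

    For every occurrence of each motif, in any frame, within a passing
    gene's CDS whose full [occurrence - flank, occurrence + flank) window
    lies inside the CDS, the gene-normalized per-nucleotide density over the
    window is collected; the profile is the per-offset median across all
    retained occurrences.  Overlapping occurrences each count once.
    """
    for motif in motifs:
        if len(motif) != 3 or any(b not in "ACGT" for b in motif):
            raise ValueError(f"motif must be a trinucleotide over ACGT, got {motif!r}")
    windows: dict[str, list[np.ndarray]] = {m: [] for m in motifs}
    for gene in genes:
        summary = gene_density(track, gene, coverage_threshold)
        if not summary.passes_coverage or summary.per_nt_avg == 0.0:
            continue
        profile = track.gene_profile(gene) / summary.per_nt_avg
        cds = extract_cds(genome, gene)
        for motif in motifs:
            pos = cds.find(motif)
            while pos != -1:
                if pos - flank >= 0 and pos + flank <= len(cds):
                    windows[motif].append(profile[pos - flank : pos + flank])
                pos = cds.find(motif, pos + 1)
    profiles = []
    offsets = np.arange(-flank, flank)
    for motif in motifs:
        occ = windows[motif]
        profiles.append(
            MotifProfile(
                motif=motif,
                offsets=offsets,
                values=np.median(np.vstack(occ), axis=0) if occ else None,
                n_occurrences=len(occ),
            )
        )
    return profiles
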
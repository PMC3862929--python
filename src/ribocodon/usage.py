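"""Codon-usage statistics: serine-codon fractions, genome-wide frequencies,
binomial enrichment of the TCN serine group, and the codon adaptation index
(CAI) after Sharp & Li.

The CAI of a gene is the geometric mean of the relative adaptiveness w of
its sense codons, where w is derived from pooled codon counts of a highly
expressed reference gene set (here, by convention, genes annotated as
"ribosomal"): within each synonymous family, w = count / max family count,
with an additive pseudocount keeping every w strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

from .codons import (
    AGY_CODONS,
    CODON_TO_AA,
    SERINE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    TCN_CODONS,
    iter_codons,
)
from .genome import Gene, Genome, extract_cds


@dataclass
class CodonUsageSummary:
    """Frame-0 codon counts of a CDS, with the serine family broken out.

    ``serine_fraction`` maps each of the six serine codons to its fraction of
    all serine codons; it is ``None`` when the CDS contains no serine codon.
    """

    per_codon_count: dict[str, int]
    serine_fraction: dict[str, float] | None
    n_serine: int


@dataclass
class GenomeCodonFrequencies:
    """Pooled codon usage across a gene set.

    ``family_fraction`` gives each sense codon's relative frequency within
    its synonymous family; ``tcn_fraction`` is the summed fraction of the
    four TCN codons within the serine family.
    """

    per_codon_count: dict[str, int]
    family_fraction: dict[str, float]
    tcn_fraction: float


@dataclass
class CaiModel:
    relative_adaptiveness: dict[str, float]
    reference_gene_ids: list[str]
    pseudocount: float


def _count_codons(cds: str) -> dict[str, int]:
    """Frame-0 codon counts, excluding the terminal stop codon."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    codons = list(iter_codons(cds))
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    for codon in codons:
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_usage(cds: str) -> CodonUsageSummary:
    """Per-codon counts of a CDS and the serine-codon fractions."""
    counts = _count_codons(cds)
    n_serine = sum(counts.get(c, 0) for c in SERINE_CODONS)
    if n_serine == 0:
        fractions = None
    else:
        fractions = {c: counts.get(c, 0) / n_serine for c in SERINE_CODONS}
    return CodonUsageSummary(counts, fractions, n_serine)


def genome_codon_frequencies(genes: list[Gene], genome: Genome) -> GenomeCodonFrequencies:
    """Pool codon counts over all genes and compute within-family fractions."""
    if not genes:
        raise ValueError("gene list is empty")
    pooled: dict[str, int] = {}
    for gene in genes:
        for codon, n in _count_codons(extract_cds(genome, gene)).items():
            pooled[codon] = pooled.get(codon, 0) + n
    family_fraction: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(pooled.get(c, 0) for c in family)
        if total > 0:
            for c in family:
                family_fraction[c] = pooled.get(c, 0) / total
    n_serine = sum(pooled.get(c, 0) for c in SERINE_CODONS)
    if n_serine == 0:
        raise ValueError("no serine codons found genome-wide")
    tcn = sum(pooled.get(c, 0) for c in TCN_CODONS) / n_serine
    return GenomeCodonFrequencies(pooled, family_fraction, tcn)


def binomial_enrichment(k_observed: int, n: int, p: float) -> float:
    """Exact binomial upper-tail probability P(X >= k_observed).

    Used to ask how surprising an observed count of TCN codons is among n
    serine codons given the genome-wide TCN fraction p.
    """
    if not 0 <= k_observed <= n:
        raise ValueError(f"need 0 <= k ({k_observed}) <= n ({n})")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"need 0 <= p <= 1, got {p}")
    return float(binom.sf(k_observed - 1, n, p))


def select_reference(genes: list[Gene], keyword: str = "ribosomal") -> list[str]:
    """Gene ids whose product annotation contains ``keyword`` (case-insensitive)."""
    needle = keyword.lower()
    return [g.id for g in genes if needle in g.product.lower()]


def build_cai_model(
    genes: list[Gene],
    genome: Genome,
    reference_ids: list[str],
    pseudocount: float = 0.5,
) -> CaiModel:
    """Relative codon adaptiveness from a reference set of highly expressed genes.

    Within each synonymous family, w(codon) = (count + pseudocount) /
    (max family count + pseudocount); the family's most used codon has w = 1
    exactly and unobserved codons stay strictly positive.
    """
    if not reference_ids:
        raise ValueError("reference gene set is empty")
    by_id = {g.id: g for g in genes}
    missing = [r for r in reference_ids if r not in by_id]
    if missing:
        raise ValueError(f"reference ids not found in annotation: {missing[:5]}")
    pooled: dict[str, int] = {}
    for rid in reference_ids:
        for codon, n in _count_codons(extract_cds(genome, by_id[rid])).items():
            pooled[codon] = pooled.get(codon, 0) + n
    w: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        max_count = max(pooled.get(c, 0) for c in family)
        for c in family:
            w[c] = (pooled.get(c, 0) + pseudocount) / (max_count + pseudocount)
    return CaiModel(w, list(reference_ids), pseudocount)


def cai(cds: str, model: CaiModel) -> float:
    """Codon adaptation index: geometric mean of w over the gene's sense codons.

    The start codon is scored as its literal codon; stop codons are excluded.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    log_sum = 0.0
    n = 0
    for codon in iter_codons(cds):
        if codon in STOP_CODONS:
            continue
        if codon not in CODON_TO_AA:
            raise ValueError(f"invalid codon {codon!r}")
        log_sum += math.log(model.relative_adaptiveness[codon])
        n += 1
    if n == 0:
        raise ValueError("no scorable codons in CDS")
    return math.exp(log_sum / n)


def tcn_enrichment_p(cds: str, genome_tcn_fraction: float) -> float:
    """Upper-tail binomial p-value for TCN over-representation in one gene.

    Convenience wrapper: counts the gene's serine codons, and asks for the
    probability of at least the observed number of TCN codons given the
    genome-wide TCN fraction among serine codons.
    """
    summary = codon_usage(cds)
    if summary.n_serine == 0:
        raise ValueError("CDS has no serine codons")
    counts = summary.per_codon_count
    k = sum(counts.get(c, 0) for c in TCN_CODONS)
    assert k + sum(counts.get(c, 0) for c in AGY_CODONS) == summary.n_serine
    return binomial_enrichment(k, summary.n_serine, genome_tcn_fraction)
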
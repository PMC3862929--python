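"""Synthetic ribosome-profiling data with known ground truth.

The generator emits genomes with strand-alternating CDSs, a ncRNA decoy,
and footprint reads whose A-site codon is sampled in proportion to a
codon-specific dwell (pause) weight.  Two output modes exist:

* ``emit_track`` paints a noise-free density track directly: the density at
  each codon's first nucleotide equals the gene's expression level times
  the codon's pause weight.  Downstream per-codon occupancy recovers the
  planted weights exactly — the oracle mode.

* ``simulate_reads`` emulates the sequencing library: footprints of
  27-33 nt whose end-trimmed span is centered (with jitter) on the A-site,
  a random ambiguous 5' base, a polyA fill to the read length, and optional
  ncRNA contamination.  Because the pipeline spreads each read's mass over
  its ~11-17 nt trimmed span, the read-mode occupancy readout is an
  attenuated, smoothed image of the planted dwell weights; see
  :func:`expected_occupancy` and the methods note.

Ground truth records, for every emitted read, the *alignable* span — the
genomic interval that survives the 5'-base discard and polyA trimming —
so round-trip tests can demand exact recovery.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .codons import SENSE_CODONS, STOP_CODONS, revcomp
from .footprints import AlignedRead, DensityTrack, Read
from .genome import Gene, Genome, extract_cds

TCN = ("TCA", "TCC", "TCG", "TCT")


@dataclass(frozen=True)
class PauseModel:
    """Relative dwell weight per sense codon (1 = baseline)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} cannot carry a pause weight")
            if w <= 0:
                raise ValueError(f"pause weight for {codon} must be > 0, got {w}")

    def weight(self, codon: str) -> float:
        return self.weights.get(codon, 1.0)


def preset_pause_model(
    condition: str, cysteine_weight: float = 1.6, **overrides: float
) -> PauseModel:
    """Pause models for the two emulated growth conditions.

    ``exponential``: all weights 1 (no codon-specific pausing).
    ``starvation``: the four TCN serine codons at 2.0, AGT at 1.3, AGC at
    1.1, matching the measured serine-codon occupancy hierarchy; both
    cysteine codons at ``cysteine_weight`` (a synthetic-only default of 1.6
    — no printed cysteine enrichment exists to copy).
    """
    if condition == "exponential":
        weights = {c: 1.0 for c in SENSE_CODONS}
    elif condition == "starvation":
        weights = {c: 1.0 for c in SENSE_CODONS}
        weights.update({c: 2.0 for c in TCN})
        weights["AGT"] = 1.3
        weights["AGC"] = 1.1
        weights["TGC"] = cysteine_weight
        weights["TGT"] = cysteine_weight
    else:
        raise ValueError(f"unknown condition {condition!r}")
    weights.update(overrides)
    return PauseModel(weights)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic library.

    ``gene_length_range`` counts internal sense codons (a gene of n sense
    codons is 3*(n+2) nt with its start and stop).  ``expression_sigma`` is
    the standard deviation (natural log) of the per-gene log-normal
    expression level, which multiplies gene length so that expected reads
    per codon, not per gene, follow the log-normal.
    """

    seed: int
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (100, 200)
    intergenic_length: int = 50
    codon_usage: dict[str, float] | None = None  # None = uniform over 61
    total_reads: int = 150_000
    read_length: int = 50
    footprint_length_range: tuple[int, int] = (27, 33)
    expression_sigma: float = 0.3
    contamination_fraction: float = 0.0
    jitter: int = 2
    end_trim: int = 8
    min_polya: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.footprint_length_range
        if hi < 2 * self.end_trim + 1:
            raise ValueError(
                f"footprint range {self.footprint_length_range} incompatible with the "
                f"{self.end_trim}-nt end-trim rule (max must be >= {2 * self.end_trim + 1})"
            )
        if lo > hi or lo < 1:
            raise ValueError(f"bad footprint length range {self.footprint_length_range}")
        if self.read_length - 1 - hi < self.min_polya:
            raise ValueError(
                "read_length too short: polyA fill must be at least "
                f"{self.min_polya} nt after the 5' base and a {hi}-nt footprint"
            )
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must be in [0, 1)")
        if self.codon_usage is not None:
            total = sum(self.codon_usage.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"codon usage probabilities sum to {total}, expected 1")
            bad = set(self.codon_usage) - set(SENSE_CODONS)
            if bad:
                raise ValueError(f"codon usage contains non-sense codons: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("gene_length_range", "footprint_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def usage_probabilities(self) -> np.ndarray:
        if self.codon_usage is None:
            return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        return np.array([self.codon_usage.get(c, 0.0) for c in SENSE_CODONS])


@dataclass
class TrueRead:
    """Ground truth for one emitted read.

    ``start``/``length`` describe the alignable span: the genomic interval
    that survives 5'-base discard and polyA trimming.  ``kept`` is False for
    contaminants and for reads whose alignable span is shorter than the
    17-nt minimum.
    """

    read_id: str
    gene_id: str | None
    contig: str | None
    start: int
    length: int
    strand: str
    kept: bool
    a_site_codon: int = -1  # codon index within the gene; -1 for contaminants


@dataclass
class SyntheticTruth:
    gene_ids: list[str]
    expression_weight: np.ndarray  # per-codon expression level per gene
    footprint_counts: np.ndarray | None = None  # genuine footprints per gene
    pause_model: PauseModel | None = None
    reads: list[TrueRead] = field(default_factory=list)

    def to_alignments(self, kept_only: bool = True) -> list[AlignedRead]:
        return [
            AlignedRead(r.read_id, r.contig, r.start, r.length, r.strand, 0)
            for r in self.reads
            if r.kept or not kept_only
        ]


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_genome(
    config: SimulationConfig,
) -> tuple[Genome, list[Gene], Genome, SyntheticTruth]:
    """Generate a genome, CDS annotation, a ncRNA decoy and a truth skeleton.

    Genes carry an ATG start and TAA stop, internal codons drawn from the
    configured usage; strands alternate +/- and genes are separated by
    random intergenic spacers.  Fully deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    usage = config.usage_probabilities()
    lo, hi = config.gene_length_range
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i in range(config.n_genes):
        spacer = _random_seq(rng, config.intergenic_length)
        parts.append(spacer)
        pos += len(spacer)
        n_sense = int(rng.integers(lo, hi + 1))
        body_idx = rng.choice(len(SENSE_CODONS), size=n_sense, p=usage)
        cds = "ATG" + "".join(SENSE_CODONS[j] for j in body_idx) + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        product = (
            f"ribosomal protein S{i}" if i % 20 == 0 else f"synthetic protein {i}"
        )
        genes.append(
            Gene(
                id=f"g{i:04d}",
                contig="chr",
                start=pos,
                end=pos + len(cds),
                strand=strand,
                product=product,
            )
        )
        pos += len(cds)
    parts.append(_random_seq(rng, config.intergenic_length))
    genome = Genome({"chr": "".join(parts)})
    ncrna = Genome({"ncrna_decoy_1": _random_seq(rng, 1500)})
    levels = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=config.n_genes)
    truth = SyntheticTruth(gene_ids=[g.id for g in genes], expression_weight=levels)
    return genome, genes, ncrna, truth


def make_codon_balanced_genome(
    n_genes: int, copies_per_codon: int = 2, seed: int = 0, intergenic_length: int = 50
) -> tuple[Genome, list[Gene], SyntheticTruth]:
    """A fixture genome in which every gene has identical codon composition.

    Each gene body is a per-gene random permutation of the 61 sense codons,
    ``copies_per_codon`` times each.  With this composition the per-codon
    occupancy of a planted pause model is recovered exactly in track mode.
    """
    rng = np.random.default_rng(seed)
    multiset = [c for c in SENSE_CODONS for _ in range(copies_per_codon)]
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i in range(n_genes):
        spacer = _random_seq(rng, intergenic_length)
        parts.append(spacer)
        pos += len(spacer)
        body = list(multiset)
        rng.shuffle(body)
        cds = "ATG" + "".join(body) + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        genes.append(
            Gene(f"g{i:04d}", "chr", pos, pos + len(cds), strand, f"balanced protein {i}")
        )
        pos += len(cds)
    parts.append(_random_seq(rng, intergenic_length))
    genome = Genome({"chr": "".join(parts)})
    truth = SyntheticTruth(
        gene_ids=[g.id for g in genes], expression_weight=np.ones(n_genes)
    )
    return genome, genes, truth


def emit_track(
    genome: Genome, genes: list[Gene], pause: PauseModel, truth: SyntheticTruth
) -> DensityTrack:
    """Noise-free density: expression level times pause weight at each codon's
    first nucleotide (transcript orientation); start and stop at baseline 1."""
    track = DensityTrack.zeros(genome)
    for gene, level in zip(genes, truth.expression_weight):
        cds = extract_cds(genome, gene)
        n = len(cds) // 3
        arr = track.data[gene.contig][gene.strand]
        for i in range(n):
            codon = cds[3 * i : 3 * i + 3]
            w = 1.0 if (i == 0 or i == n - 1) else pause.weight(codon)
            g = gene.start + 3 * i if gene.strand == "+" else gene.end - 1 - 3 * i
            arr[g] += level * w
    track.n_reads_assigned = track.total_mass()
    return track


def _sample_footprints(
    rng: np.random.Generator,
    genome: Genome,
    genes: list[Gene],
    pause: PauseModel,
    config: SimulationConfig,
    n_footprints: int,
    levels: np.ndarray | None = None,
    expression_multiplier: np.ndarray | None = None,
):
    """Sample (gene index, transcript read start, length, A-site codon) arrays.

    The footprint is placed so that its end-trimmed span is centered on the
    first nucleotide of the sampled A-site codon, shifted by a uniform
    jitter and clipped to the CDS.
    """
    cds_list = [extract_cds(genome, g) for g in genes]
    n_codons = np.array([len(c) // 3 for c in cds_list])
    if levels is None:
        levels = _current_levels(genes, config, rng)
    probs = levels * n_codons
    if expression_multiplier is not None:
        probs = probs * np.asarray(expression_multiplier)
    probs = probs / probs.sum()
    per_gene = rng.multinomial(n_footprints, probs)
    lo, hi = config.footprint_length_range
    t = config.end_trim
    gene_idx = np.empty(n_footprints, dtype=np.int64)
    read_start = np.empty(n_footprints, dtype=np.int64)
    lengths = np.empty(n_footprints, dtype=np.int64)
    a_site = np.empty(n_footprints, dtype=np.int64)
    out = 0
    for gi, n_g in enumerate(per_gene):
        if n_g == 0:
            continue
        cds = cds_list[gi]
        n = n_codons[gi]
        w = np.array(
            [
                1.0 if (i == 0 or i == n - 1) else pause.weight(cds[3 * i : 3 * i + 3])
                for i in range(n)
            ]
        )
        ci = rng.choice(n, size=n_g, p=w / w.sum())
        L = rng.integers(lo, hi + 1, size=n_g)
        m = L - 2 * t
        jit = rng.integers(-config.jitter, config.jitter + 1, size=n_g)
        rs = 3 * ci - (m // 2) + jit - t
        rs = np.clip(rs, 0, len(cds) - L)
        sl = slice(out, out + n_g)
        gene_idx[sl] = gi
        read_start[sl] = rs
        lengths[sl] = L
        a_site[sl] = ci
        out += n_g
    return gene_idx, read_start, lengths, a_site, per_gene, levels


def _current_levels(
    genes: list[Gene], config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    # expression levels are drawn here so that footprint sampling is fully
    # reproducible from the config seed alone
    return rng.lognormal(0.0, config.expression_sigma, size=len(genes))


def simulate_footprints(
    genome: Genome,
    genes: list[Gene],
    pause: PauseModel,
    config: SimulationConfig,
    levels: np.ndarray | None = None,
    expression_multiplier: np.ndarray | None = None,
) -> tuple[list[AlignedRead], SyntheticTruth]:
    """Fast read-mode path: sample footprints and return them directly as
    mismatch-free alignments, skipping sequence materialization.

    The alignments carry the full (pre-trim) footprint span; use
    :func:`simulate_reads` when the FASTQ-level trimming round trip matters.
    ``levels`` overrides the per-gene expression draw (so two samples can
    share a transcriptome) and ``expression_multiplier`` plants per-gene
    induction on top of it.
    """
    rng = np.random.default_rng(config.seed)
    n_fp = config.total_reads
    gene_idx, rs, L, a_site, per_gene, levels = _sample_footprints(
        rng, genome, genes, pause, config, n_fp, levels, expression_multiplier
    )
    alignments = []
    for k in range(n_fp):
        gene = genes[gene_idx[k]]
        if gene.strand == "+":
            g0 = gene.start + rs[k]
        else:
            g0 = gene.end - rs[k] - L[k]
        alignments.append(
            AlignedRead(f"fp{k:07d}", gene.contig, int(g0), int(L[k]), gene.strand, 0)
        )
    truth = SyntheticTruth(
        gene_ids=[g.id for g in genes],
        expression_weight=levels,
        footprint_counts=per_gene,
        pause_model=pause,
    )
    return alignments, truth


def simulate_reads(
    genome: Genome,
    genes: list[Gene],
    pause: PauseModel,
    config: SimulationConfig,
    ncrna: Genome | None = None,
) -> tuple[list[Read], SyntheticTruth]:
    """Emulate the sequencing library read by read.

    Each genuine read is one random 5' base, the footprint sequence, and a
    polyA fill to ``read_length``; a ``contamination_fraction`` of reads are
    ncRNA slices dressed the same way.  Truth records each read's alignable
    span (what survives trimming), with reads whose span falls below 17 nt
    flagged as discarded.
    """
    if config.contamination_fraction > 0 and ncrna is None:
        raise ValueError("contamination requested but no ncRNA genome supplied")
    rng = np.random.default_rng(config.seed)
    n_contam = (
        int(rng.binomial(config.total_reads, config.contamination_fraction))
        if config.contamination_fraction > 0
        else 0
    )
    n_fp = config.total_reads - n_contam
    gene_idx, rs, L, a_site, per_gene, levels = _sample_footprints(
        rng, genome, genes, pause, config, n_fp
    )
    cds_list = [extract_cds(genome, g) for g in genes]
    polya_re = re.compile("A{%d,}" % config.min_polya)
    reads: list[Read] = []
    truth_reads: list[TrueRead] = []
    five_prime = _BASES[rng.integers(0, 4, config.total_reads)]
    for k in range(n_fp):
        gi = int(gene_idx[k])
        gene = genes[gi]
        fragment = cds_list[gi][rs[k] : rs[k] + L[k]]
        fill = "A" * (config.read_length - 1 - int(L[k]))
        seq = five_prime[k] + fragment + fill
        read_id = f"read{k:07d}"
        reads.append(Read(read_id, seq, "I" * len(seq)))
        # alignable span: emulate 5'-discard + polyA trim on this read
        match = polya_re.search(fragment + fill)
        cut = max(match.start() - 1, 0) if match else len(fragment)
        kept = cut >= 2 * config.end_trim + 1
        if gene.strand == "+":
            g0 = gene.start + int(rs[k])
        else:
            g0 = gene.end - int(rs[k]) - cut
        truth_reads.append(
            TrueRead(read_id, gene.id, gene.contig, int(g0), cut, gene.strand,
                     kept, int(a_site[k]))
        )
    if n_contam:
        nc_names = list(ncrna.contigs)
        lo, hi = config.footprint_length_range
        for j in range(n_contam):
            name = nc_names[int(rng.integers(0, len(nc_names)))]
            seq_nc = ncrna.contigs[name]
            ln = int(rng.integers(lo, hi + 1))
            p0 = int(rng.integers(0, len(seq_nc) - ln + 1))
            slice_ = seq_nc[p0 : p0 + ln]
            fill = "A" * (config.read_length - 1 - ln)
            read_id = f"contam{j:07d}"
            reads.append(Read(read_id, five_prime[n_fp + j] + slice_ + fill, None))
            truth_reads.append(TrueRead(read_id, None, name, p0, ln, "+", False))
    truth = SyntheticTruth(
        gene_ids=[g.id for g in genes],
        expression_weight=levels,
        footprint_counts=per_gene,
        pause_model=pause,
        reads=truth_reads,
    )
    return reads, truth


def expected_occupancy(pause: PauseModel, config: SimulationConfig) -> dict[str, float]:
    """First-order prediction of the read-mode occupancy readout.

    The center-weighted density estimator spreads each read over its
    trimmed span of m = L - 2*end_trim positions, so the first-nucleotide
    density of a codon retains only K0 = E[3/m] of its own dwell signal,
    the rest being a local average of its neighbours.  For a codon of dwell
    weight w embedded in baseline-weight context the expected
    median-relative readout is approximately 1 + K0*(w - 1).
    """
    lo, hi = config.footprint_length_range
    ms = np.arange(lo, hi + 1) - 2 * config.end_trim
    ms = ms[ms >= 1]
    k0 = float(np.mean(3.0 / ms))
    return {c: 1.0 + k0 * (pause.weight(c) - 1.0) for c in SENSE_CODONS}


# ---------------------------------------------------------------------------
# plain-text writers for the simulator's outputs


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as out:
        for name in sorted(genome.contigs):
            out.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_gff3(genes: list[Gene], path: str, source: str = "ribocodon-sim") -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.id};product={gene.product}"
            out.write(
                f"{gene.contig}\t{source}\tCDS\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t0\t{attrs}\n"
            )


def write_fastq(reads: list[Read], path: str) -> None:
    with open(path, "w") as out:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            out.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fastq(path: str) -> list[Read]:
    from Bio import SeqIO

    return [
        Read(rec.id, str(rec.seq), "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(path, "fastq")
    ]


def write_truth_genes(truth: SyntheticTruth, path: str) -> None:
    with open(path, "w") as out:
        out.write("gene_id\texpression_weight\tfootprint_count\n")
        counts = (
            truth.footprint_counts
            if truth.footprint_counts is not None
            else np.zeros(len(truth.gene_ids), dtype=int)
        )
        for gid, w, n in zip(truth.gene_ids, truth.expression_weight, counts):
            out.write(f"{gid}\t{w:.8g}\t{int(n)}\n")


def write_truth_reads(truth: SyntheticTruth, path: str) -> None:
    with open(path, "w") as out:
        out.write("read_id\tgene_id\tcontig\tstart\tlength\tstrand\tkept\ta_site_codon\n")
        for r in truth.reads:
            out.write(
                f"{r.read_id}\t{r.gene_id or '.'}\t{r.contig or '.'}\t{r.start}\t"
                f"{r.length}\t{r.strand}\t{int(r.kept)}\t{r.a_site_codon}\n"
            )
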
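"""Independent brute-force reference implementations used as oracles.

These deliberately avoid the production code paths: explicit Python loops,
their own reverse complement, their own median.  They are slow and simple on
purpose.
"""

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SENSE = sorted(
    c1 + c2 + c3
    for c1 in "ACGT" for c2 in "ACGT" for c3 in "ACGT"
    if c1 + c2 + c3 not in ("TAA", "TAG", "TGA")
)


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def median(values):
    vs = sorted(values)
    n = len(vs)
    if n == 0:
        raise ValueError("median of empty list")
    mid = n // 2
    return vs[mid] if n % 2 else (vs[mid - 1] + vs[mid]) / 2.0


def gene_cds(contig_seq, start, end, strand):
    s = contig_seq[start:end]
    return rc(s) if strand == "-" else s


def gene_profile(track_arrays, contig, start, end, strand):
    """Transcript-oriented per-nt density list for one gene."""
    arr = track_arrays[contig][strand]
    values = [arr[i] for i in range(start, end)]
    return values[::-1] if strand == "-" else values


def per_gene_values(track_arrays, genome_contigs, gene):
    """Triple-loop reference for per-codon relative occupancy of one gene."""
    contig, start, end, strand = gene.contig, gene.start, gene.end, gene.strand
    profile = gene_profile(track_arrays, contig, start, end, strand)
    avg = sum(profile) / len(profile)
    if avg == 0:
        raise ValueError("zero density")
    cds = gene_cds(genome_contigs[contig], start, end, strand)
    n = len(cds) // 3
    sums, counts = {}, {}
    for i in range(n):
        codon = cds[3 * i : 3 * i + 3]
        key = "START" if i == 0 else "STOP" if i == n - 1 else codon
        sums[key] = sums.get(key, 0.0) + profile[3 * i]
        counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] / avg for k in sums}


def codon_density_table(track_arrays, genome_contigs, genes, coverage_threshold=1.0):
    """Reference genome-wide median and median-relative occupancy per codon."""
    collected = {}
    for gene in genes:
        profile = gene_profile(
            track_arrays, gene.contig, gene.start, gene.end, gene.strand
        )
        per_codon_avg = 3.0 * sum(profile) / len(profile)
        if per_codon_avg < coverage_threshold:
            continue
        for key, v in per_gene_values(track_arrays, genome_contigs, gene).items():
            collected.setdefault(key, []).append(v)
    medians = {k: median(vs) for k, vs in collected.items()}
    mom = median([medians[c] for c in SENSE if c in medians])
    rel = {k: m / mom for k, m in medians.items()}
    return medians, rel


def binomial_upper_tail_by_enumeration(k, n, p):
    """P(X >= k) by summing over all 2^n outcome sequences."""
    total = 0.0
    for outcome in product((0, 1), repeat=n):
        successes = sum(outcome)
        if successes >= k:
            total += (p ** successes) * ((1 - p) ** (n - successes))
    return total


def pearson_r2(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy * sxy / (sxx * syy)
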
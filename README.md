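# ribocodon

Codon-resolution analysis of bacterial ribosome profiling (ribo-seq) data,
plus a synthetic footprint generator with known codon pause weights.

## The problem

Ribosome profiling sequences the ~27–33 nt mRNA fragments protected by
translating ribosomes; local read density is proportional to ribosome
occupancy and inversely related to local elongation speed.  When a specific
amino acid runs short — serine is among the first depleted at the end of
exponential growth in *Bacillus subtilis* — ribosomes dwell longer at the
codons read by the starved tRNAs, and that dwell differs *between
synonymous codons*: the four UCN serine codons slow down much more than
AGC/AGU.  Detecting such codon-specific pausing genome-wide requires
careful bookkeeping: A-site-proximal density assignment, per-gene
normalization, coverage filtering, and robust (median-based) summaries
across genes.  `ribocodon` packages that bookkeeping as a tested library
and CLI for anyone analyzing bacterial ribo-seq at codon resolution, and
ships a simulator that plants known pause weights so the whole pipeline can
be validated end to end.

## The statistic

For a gene g with per-nucleotide density profile d(·) and mean density
d̄_g (start and stop codons included), the occupancy of codon c in g is

    occ_g(c) = mean over occurrences of c of d(first nt of c) / d̄_g

so occ = 1 means no over- or under-representation.  Genome-wide, over genes
with ≥ 1 read per codon,

    median_relative(c) = median_g occ_g(c) / median over the 61 sense codons of median_g occ_g(·)

This is the headline per-codon enrichment.  Density itself follows the
center-weighting convention: each alignment of length L is trimmed 8 nt
from each end (approximating the A-site region) and spreads 1/(L−16) over
the remaining span, so total track mass equals the read count.

Differential expression between samples uses median-subtracted log2
fold-changes of per-gene counts (≥ 100 reads in at least one sample), the
preferential-induction set is `Δ(adjusted log2 FC) ≥ log2(10)` between two
comparisons, and codon-usage statistics include exact binomial TCN
enrichment and the Sharp–Li codon adaptation index (CAI).

## Worked example

```python
from ribocodon import *
from ribocodon.simulate import (
    make_codon_balanced_genome, SimulationConfig, simulate_footprints,
)

# noise-free oracle: every gene has identical codon composition and the
# starvation pause model (TCN=2.0, AGT=1.3, AGC=1.1) is painted directly
genome, genes, truth = make_codon_balanced_genome(40, copies_per_codon=2, seed=7)
track = emit_track(genome, genes, preset_pause_model("starvation"), truth)
table = genomewide_codon_density(track, genes, genome)
for codon in ("TCA", "TCC", "TCG", "TCT", "AGT", "AGC", "GGC"):
    print(f"{codon}  median_relative = {table.median_relative[codon]:.3f}")

# stochastic read mode: 300 genes x ~500 footprints/gene
config = SimulationConfig(seed=7)
genome, genes, _, _ = make_genome(config)
alignments, _ = simulate_footprints(genome, genes,
                                    preset_pause_model("starvation"), config)
noisy = genomewide_codon_density(build_density_track(alignments, genome),
                                 genes, genome)
print(f"read mode: TCA {noisy.median_relative['TCA']:.3f}  "
      f"AGT {noisy.median_relative['AGT']:.3f}  "
      f"AGC {noisy.median_relative['AGC']:.3f}")
```

prints

```
TCA  median_relative = 2.000
TCC  median_relative = 2.000
TCG  median_relative = 2.000
TCT  median_relative = 2.000
AGT  median_relative = 1.300
AGC  median_relative = 1.100
GGC  median_relative = 1.000
read mode: TCA 1.221  AGT 1.073  AGC 1.032
```

Track mode recovers the planted weights exactly.  In read mode the
enrichment hierarchy survives but is attenuated (2.0 → ~1.2): the
center-weighted estimator spreads each read over its ~11–17 nt trimmed
span, so codon-scale contrast is smoothed by a factor of roughly
E[3/m] ≈ 0.22 — a property of the estimator worth keeping in mind when
interpreting measured enrichments as dwell times.  See
`docs/methods.md` for the analysis.

The same operations are available from the shell:

```sh
ribocodon simulate --config sim.yaml --condition starvation --mode reads -o out/
ribocodon trim --fastq out/reads.fastq -o trimmed.fastq
ribocodon density --sam aln.sam --genome out/genome.fa -o track
ribocodon density-by-codon --track-prefix track --genome out/genome.fa --gff out/genes.gff3
ribocodon sd-profile --track-prefix track --genome out/genome.fa --gff out/genes.gff3 --motifs AGG,GGA,GAG,GGT,GTG,TGG
ribocodon codonstats --genome out/genome.fa --gff out/genes.gff3 -o usage.tsv
ribocodon foldchange --sam-a a.sam --sam-b b.sam --genome g.fa --gff a.gff3 -o fc.tsv
ribocodon compare --fc1 fc_biofilm.tsv --fc2 fc_starvation.tsv --fold 10
```

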
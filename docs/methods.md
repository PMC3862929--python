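# Methods

## Scope and model

`ribocodon` implements a codon-resolution analysis of bacterial ribosome
profiling (ribo-seq) data, together with a synthetic data generator that
plants known codon-specific pause weights so every stage of the pipeline can
be validated against ground truth.  The biological question it serves is
whether particular synonymous codons — canonically the four UCN serine
codons during serine depletion and biofilm entry in *Bacillus subtilis* —
carry elevated ribosome occupancy, i.e. are decoded more slowly.

The processing chain follows the standard bacterial ribo-seq conventions:

1. **Library trimming.** Each read loses its ambiguous first 5′ base; a run
   of ≥ `min_polya` (default 10) adenines marks the polyA library tail and
   everything from one nucleotide *before* the run onward is discarded (the
   junction base cannot be distinguished from a templated A).  Reads shorter
   than `min_keep` = 17 nt are dropped — 17 is the shortest length for which
   the A-site trim below leaves one density position.
2. **ncRNA filtering** by exact substring match (either strand) against the
   supplied non-coding RNA records.
3. **Alignment** — either ingestion of ungapped SAM records (NM tag as the
   mismatch count; records with indels or clipping are skipped), or a naive
   exact-match unique-hit aligner adequate for mismatch-free synthetic
   reads.  Alignments with more than `max_mismatches` = 2 mismatches are
   discarded.  Multi-mapping reads are dropped: uniqueness keeps the density
   interpretable.
4. **Center-weighted density.** An alignment of length L is trimmed by
   `end_trim` = 8 nt from each end to approximate the ribosome A-site
   region, and contributes 1/(L − 16) read-equivalents to each position of
   the remaining span, on its own strand.  Total track mass therefore equals
   the number of contributing alignments exactly (asserted to 1e-9
   relative).  Strand-specific assignment is used throughout: footprints
   are sense-strand by construction of the protocol.

## Per-codon occupancy

For a gene with average per-nucleotide density `d̄` (computed over the whole
CDS, start and stop codons included), the occupancy of a codon is the
density at the codon's **first nucleotide** in transcript orientation
(highest genomic coordinate on the minus strand), averaged over the codon's
occurrences in the gene and divided by `d̄`.  A codon with no over- or
under-representation scores exactly 1; a uniform track scores 1 at every
key (the normalization identity, tested).  The start codon is keyed
`START` irrespective of identity; the terminal codon is keyed `STOP`;
neither enters the 61-sense-codon summaries, but both contribute to `d̄`, so
strong start/stop peaks deflate all other codons slightly.

Genome-wide, only genes with average density of at least
`coverage_threshold` = 1 read per codon are used (the comparison is ≥).
Each codon's per-gene values are summarized by their **median across
genes**; genes lacking a codon contribute nothing to that codon (absence is
not evidence of zero occupancy).  The reported statistic is the
`median_relative`: each codon's median divided by the median over the 61
sense-codon medians, so the table's own median is 1 by construction.

The gene-half split assigns each codon by index to the first ⌈C/2⌉ or the
remaining codons of a C-codon gene (first half takes the extra codon on
ties) and reuses the whole-gene `d̄` for normalization, so the two halves
are directly comparable.

Motif metagene profiles (for Shine–Dalgarno-like trinucleotides, whose
identities are a configuration input) take every occurrence of the motif in
any frame within a passing gene, require the full ±`flank` (default 30 nt)
window to lie inside the CDS (truncated windows are dropped, not padded),
normalize the window by the gene's `d̄`, and report the per-offset median
across occurrences.  Overlapping occurrences each count once.

## Fold-changes and the preferential set

Counts per gene assign each end-trimmed alignment to the unique same-strand
gene containing its span midpoint; midpoints covered by two overlapping
genes count for neither.  For two samples, `log2fc_raw = log2(c_a / c_b)`
(with an optional pseudocount; by default zero counts propagate as ±inf/nan
and are excluded), a gene qualifies when max(c_a, c_b) ≥ `min_reads` = 100,
and the median raw value over qualifying finite genes is subtracted — the
adjusted values have median 0 exactly, which is the only normalization
applied.  The preferential set between two comparisons collects genes whose
adjusted values differ by at least log2(`fold_threshold`), i.e. a ratio of
ratios ≥ 10 by default; the criterion is monotone in the threshold.
Cross-condition agreement is the squared Pearson correlation of adjusted
values over shared qualifying genes.

## Codon-usage statistics

Codon counts exclude the terminal stop codon.  Serine-codon fractions are
reported over the six serine codons; the TCN enrichment p-value is the
exact binomial upper tail P(X ≥ k) for k observed TCN codons among n serine
codons at the genome-wide TCN fraction p (computed by `scipy.stats.binom.sf`
and cross-checked in the tests against exhaustive 2ⁿ enumeration for all
n ≤ 12).  For the worked configuration k = 10, n = 12, p = 0.66 the exact
tail is 0.16872.

CAI follows Sharp & Li: within each synonymous family the relative
adaptiveness is w = (count + q)/(max family count + q) with pseudocount
q = 0.5 (configurable) over a reference set of highly expressed genes —
selectable by a case-insensitive "ribosomal" product-annotation keyword or
supplied directly.  A gene's CAI is the geometric mean of w over all its
sense codons, the start codon scored as written, stop codons excluded,
single-codon families included (w = 1, no effect).  CAI is invariant under
codon permutation and self-concatenation, lies in (0, 1], and never
increases when a codon is replaced by a lower-w synonym (all tested).

## The synthetic generator

`make_genome` emits strand-alternating CDSs (ATG start, TAA stop, internal
codons from a configurable usage distribution, uniform over the 61 sense
codons by default), random intergenic spacers, and one random ncRNA decoy
record; everything is reproducible byte-for-byte from the seed.  Default
conditions: 300 genes of 100–200 sense codons, 150 000 footprints (~500 per
gene, comfortably above the 1-read-per-codon coverage filter), per-gene
log-normal expression dispersion σ = 0.3 (natural log), length-adjusted so
that expected reads *per codon* follow the log-normal, keeping the coverage
filter's pass rate controllable.

Pausing acts at the A-site codon only — the minimal model consistent with
starvation-limited tRNA delivery; no nascent-chain, mRNA-structure or MNase
sequence-bias effects are modeled.  The `starvation` preset plants dwell
weights 2.0 at TCA/TCC/TCG/TCT, 1.3 at AGT, 1.1 at AGC, 1.6 at both
cysteine codons (the cysteine value is a synthetic-only default; no printed
enrichment exists to copy), all others 1; `exponential` is flat.

Two emission modes:

* **Track mode** paints expression × dwell weight directly at each codon's
  first nucleotide (start/stop at baseline).  Downstream occupancy recovers
  the planted weights *exactly*: for a gene with codon weights w and C
  codons the per-gene value is 3C·w/(Σw + 2), so after median-relative
  normalization a fixture in which every gene has identical codon
  composition (`make_codon_balanced_genome`) reads 2.0/1.3/1.1 to 1e-9.
* **Read mode** samples, per footprint, a gene (∝ expression × length), an
  A-site codon (∝ dwell weight), a footprint length uniform on 27–33 nt,
  and places the footprint so its 8-nt-trimmed span is centered on the
  A-site first nucleotide with ±2 nt uniform jitter, clipped to the CDS.
  Reads are 1 random 5′ base + footprint + polyA fill to 50 nt; a
  configurable fraction are ncRNA slices dressed identically.

Because the polyA trim sacrifices the base adjacent to the run, the last
footprint base (plus any templated trailing adenines) is unrecoverable by
construction.  Truth therefore records each read's **alignable span** — the
interval that survives trimming, computed at generation time with the same
rule — and flags reads whose span falls below 17 nt as discarded.  Against
this truth the round trip (simulate → trim → exact-align) is exact: 100%
of kept reads are recovered with identical coordinates.

## Attenuation of the read-mode occupancy readout

The center-weighted estimator is, at codon scale, a moving average: a read
whose trimmed span has length m covers the first nucleotides of about m/3
consecutive codons and deposits 1/m on each.  A codon therefore retains
only K₀ = E[3/m] of its own dwell signal — about 0.22 for the default
27–33 nt footprints — the remainder being a local average over its
neighbours.  For an isolated elevated codon in baseline context the
expected readout is approximately 1 + K₀(w − 1) (`expected_occupancy`),
and no nonnegative read distribution under this geometry can produce sharp
codon-to-codon contrast, because any span covering a codon's first
nucleotide also covers its neighbours'.  Consequences, all confirmed by
simulation and asserted in the test suite:

* a planted dwell weight of 2.0 reads out near 1.19; 1.3 near 1.06; 1.1
  near 1.02 (read mode, 300 genes × 500 reads/gene);
* the UCN > AGU ordering is robust, but the AGC enrichment (+0.02 after
  attenuation) sits inside the baseline codon scatter (±0.03) at this
  depth, so the strict four-level hierarchy is not reliably resolved;
* the flat null model stays within [0.96, 1.04] across all 61 codons;
* track mode, which bypasses read geometry, recovers weights exactly.

The corollary for real data is worth stating: measured median-relative
enrichments produced by this estimator are *attenuated* images of the
underlying dwell-time differences, so a measured ~2× occupancy ratio
implies a considerably larger true dwell contrast.  Passing the read-mode
tests shows the pipeline faithfully measures what the estimator can
measure; it does not show that measured enrichment equals dwell ratio.

## Numerical choices and degenerate inputs

Medians use numpy's midpoint interpolation for even counts.  Genes with
zero total density cannot be normalized and raise an error (callers filter
by coverage first).  Empty motif-occurrence sets yield a profile flagged
empty rather than NaNs.  The validation suite runs at deliberately modest
problem sizes — 20 read-mode replicates of 300 genes × 150 000 reads for
the recovery studies, 200 genes × 50 000 reads × 20 fixtures for the
brute-force oracle comparison — chosen as the smallest scales at which the
medians are stable to ~1%.

## Known limitations

No sequencing-error or quality model; no gapped alignment; no UMI/duplicate
handling; ncRNA filtering is exact-substring (real libraries should be
pre-filtered with an aligner); no tRNA-adaptation (tAI) modeling; no
statistical testing of individual pause sites (medians only, following the
analysis this package reimplements); the simulator's contamination and
polyA artifacts are exact rather than error-bearing, so filter performance
on real data will be somewhat worse than the synthetic round trip suggests.
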
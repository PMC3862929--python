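"""Genome/annotation loading, codon extraction and codon-usage statistics."""

import math

import pytest
from hypothesis import given, strategies as st

import reference_impls as ref
from ribocodon import (
    Gene,
    Genome,
    binomial_enrichment,
    build_cai_model,
    cai,
    codon_usage,
    extract_cds,
    genome_codon_frequencies,
    read_annotation,
    read_genome,
    revcomp,
    select_reference,
)
from ribocodon.simulate import make_genome, SimulationConfig, write_fasta, write_gff3


class TestReadGenome:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n")
        assert read_genome(p).contigs == {"c1": "ACGT"}

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgt\n")
        assert read_genome(p).contigs == {"c1": "ACGT"}

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome(p)

    def test_ambiguous_base_names_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACNT\n")
        with pytest.raises(ValueError, match="c1"):
            read_genome(p)


class TestReadAnnotation:
    GFF = (
        "##gff-version 3\n"
        "c1\tsrc\tCDS\t1\t12\t.\t+\t0\tID=gA;product=widget\n"  # 0..12
        "c1\tsrc\tCDS\t21\t29\t.\t-\t0\tID=gB;product=ribosomal protein\n"
        "c1\tsrc\tCDS\t1\t10\t.\t+\t0\tID=gBad;product=len10\n"  # skipped
    )

    def test_coordinates_and_skipping(self, tmp_path, caplog):
        gff = tmp_path / "a.gff3"
        gff.write_text(self.GFF)
        genome = Genome({"c1": "A" * 40})
        genes = read_annotation(gff, genome)
        assert [g.id for g in genes] == ["gA", "gB"]
        assert (genes[0].start, genes[0].end, genes[0].strand) == (0, 12, "+")
        assert (genes[1].start, genes[1].end, genes[1].strand) == (20, 29, "-")
        assert genes[1].product == "ribosomal protein"

    def test_cds_past_contig_end_errors(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("##gff-version 3\nc1\tsrc\tCDS\t1\t12\t.\t+\t0\tID=g1\n")
        with pytest.raises(ValueError):
            read_annotation(gff, Genome({"c1": "ACGTACGT"}))

    def test_no_cds_features(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("##gff-version 3\nc1\tsrc\tgene\t1\t12\t.\t+\t.\tID=g1\n")
        assert read_annotation(gff, Genome({"c1": "A" * 20})) == []

    def test_round_trip_with_simulator_writers(self, tmp_path):
        config = SimulationConfig(seed=11, n_genes=6, gene_length_range=(20, 30),
                                  total_reads=10)
        genome, genes, _, _ = make_genome(config)
        write_fasta(genome, str(tmp_path / "g.fa"))
        write_gff3(genes, str(tmp_path / "g.gff3"))
        genome2 = read_genome(tmp_path / "g.fa")
        genes2 = read_annotation(tmp_path / "g.gff3", genome2)
        assert genome2.contigs == genome.contigs
        assert [(g.id, g.start, g.end, g.strand) for g in genes2] == [
            (g.id, g.start, g.end, g.strand) for g in genes
        ]


class TestExtractCds:
    def test_plus_strand(self):
        genome = Genome({"c1": "ATGTCATAA"})
        assert extract_cds(genome, Gene("g", "c1", 0, 9, "+")) == "ATGTCATAA"

    def test_minus_strand_reverse_complement(self):
        genome = Genome({"c1": "TTATGACAT"})
        assert extract_cds(genome, Gene("g", "c1", 0, 9, "-")) == "ATGTCATAA"

    def test_out_of_bounds_errors(self):
        genome = Genome({"c1": "ATGTCA"})
        with pytest.raises(ValueError):
            extract_cds(genome, Gene("g", "c1", 0, 9, "+"))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_strand_round_trip(self, seed):
        """Flipping the genome and the gene strand leaves the CDS unchanged."""
        import numpy as np

        rng = np.random.default_rng(seed)
        n = 30
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        genome = Genome({"c1": seq})
        gene = Gene("g", "c1", 6, 27, "+")
        flipped_genome = Genome({"c1": revcomp(seq)})
        flipped_gene = Gene("g", "c1", n - 27, n - 6, "-")
        assert extract_cds(genome, gene) == extract_cds(flipped_genome, flipped_gene)


class TestCodonUsage:
    def test_sinr_like_serine_composition(self):
        # 12 serine codons, 10 of them TCN: the gene-level quantity behind the
        # TCN-enrichment test
        serines = ["TCA"] * 3 + ["TCC"] * 3 + ["TCG"] * 2 + ["TCT"] * 2 + ["AGC", "AGT"]
        cds = "ATG" + "".join(serines) + "GGC" + "TAA"
        summary = codon_usage(cds)
        assert summary.n_serine == 12
        tcn = sum(summary.serine_fraction[c] for c in ("TCA", "TCC", "TCG", "TCT"))
        assert tcn == pytest.approx(10 / 12, abs=1e-12)
        assert sum(summary.serine_fraction.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_serine_flagged(self):
        summary = codon_usage("ATGTAA")
        assert summary.n_serine == 0
        assert summary.serine_fraction is None

    def test_single_serine(self):
        summary = codon_usage("ATGTCATAA")
        assert summary.n_serine == 1
        assert summary.serine_fraction["TCA"] == 1.0

    def test_length_error(self):
        with pytest.raises(ValueError):
            codon_usage("ATGT")


class TestGenomeFrequencies:
    def test_pooled_tcn_split(self):
        genome = Genome({"c1": "ATGTCATCAAGCAGCTAA" + "ATGTCATAA"})
        genes = [Gene("g1", "c1", 0, 18, "+"), Gene("g2", "c1", 18, 27, "+")]
        freqs = genome_codon_frequencies(genes, genome)
        # pooled serine codons: TCA x3, AGC x2 -> TCN split 3/5
        assert freqs.tcn_fraction == pytest.approx(3 / 5)

    def test_single_gene_all_tcn(self):
        genome = Genome({"c1": "ATGTCATAA"})
        assert genome_codon_frequencies(
            [Gene("g", "c1", 0, 9, "+")], genome
        ).tcn_fraction == 1.0

    def test_no_serine_errors(self):
        genome = Genome({"c1": "ATGGGCTAA"})
        with pytest.raises(ValueError):
            genome_codon_frequencies([Gene("g", "c1", 0, 9, "+")], genome)

    def test_uniform_usage_genome_tcn_near_two_thirds(self):
        """Uniform codon usage gives a TCN serine split near 4/6, checked
        against a direct count over the emitted CDS strings."""
        config = SimulationConfig(seed=5, n_genes=40, gene_length_range=(150, 250),
                                  total_reads=10)
        genome, genes, _, _ = make_genome(config)
        freqs = genome_codon_frequencies(genes, genome)
        # independent count straight off the CDS strings
        n_tcn = n_ser = 0
        for g in genes:
            cds = ref.gene_cds(genome.contigs[g.contig], g.start, g.end, g.strand)
            for i in range(0, len(cds) - 3, 3):
                codon = cds[i : i + 3]
                if codon in ("TCA", "TCC", "TCG", "TCT", "AGC", "AGT"):
                    n_ser += 1
                    n_tcn += codon.startswith("TC")
        assert freqs.tcn_fraction == pytest.approx(n_tcn / n_ser, abs=1e-12)
        assert abs(freqs.tcn_fraction - 4 / 6) < 0.05


class TestBinomialEnrichment:
    def test_full_tail_is_one(self):
        assert binomial_enrichment(0, 5, 0.3) == pytest.approx(1.0, abs=1e-12)

    def test_two_of_two(self):
        assert binomial_enrichment(2, 2, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            binomial_enrichment(5, 2, 0.5)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 2, 1.5)

    @given(st.integers(1, 12), st.sampled_from([0.1, 0.34, 0.5, 0.66, 0.9]))
    def test_matches_exhaustive_enumeration(self, n, p):
        for k in range(n + 1):
            expected = ref.binomial_upper_tail_by_enumeration(k, n, p)
            assert binomial_enrichment(k, n, p) == pytest.approx(expected, abs=1e-12)

    def test_complement_identity(self):
        from scipy.stats import binom

        for k, n, p in [(3, 7, 0.4), (10, 12, 0.66), (1, 4, 0.9)]:
            lower = float(binom.cdf(k - 1, n, p))
            assert binomial_enrichment(k, n, p) + lower == pytest.approx(1.0, abs=1e-12)


def _genome_of_genes(cds_list):
    seq = "".join(cds_list)
    genome = Genome({"c1": seq})
    genes, pos = [], 0
    for i, cds in enumerate(cds_list):
        genes.append(Gene(f"g{i}", "c1", pos, pos + len(cds), "+", f"protein {i}"))
        pos += len(cds)
    return genome, genes


class TestCai:
    def test_pseudocount_formula(self):
        # reference gene with serine counts {TCT: 8, others 0}
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 8 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"], pseudocount=0.5)
        assert model.relative_adaptiveness["TCT"] == 1.0
        assert model.relative_adaptiveness["TCA"] == pytest.approx(0.5 / 8.5)

    def test_tied_family_counts_both_one(self):
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 4 + "TCA" * 4 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"])
        assert model.relative_adaptiveness["TCT"] == 1.0
        assert model.relative_adaptiveness["TCA"] == 1.0

    def test_max_w_per_family_is_one(self):
        genome, genes = _genome_of_genes(["ATGGGCTCTTTGAAACGTTAA"])
        model = build_cai_model(genes, genome, ["g0"])
        from ribocodon.codons import SYNONYMOUS_FAMILIES

        for family in SYNONYMOUS_FAMILIES.values():
            assert max(model.relative_adaptiveness[c] for c in family) == 1.0

    def test_select_reference_keyword(self):
        genome, genes = _genome_of_genes(
            ["ATGTCTTAA", "ATGTCATAA", "ATGGGCTAA", "ATGAAATAA"]
        )
        genes[0] = Gene("g0", "c1", 0, 9, "+", "30S ribosomal protein S1")
        genes[2] = Gene("g2", "c1", 18, 27, "+", "Ribosomal RNA methylase")
        assert select_reference(genes) == ["g0", "g2"]

    def test_cai_values_and_identities(self):
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 8 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"], pseudocount=0.5)
        w = model.relative_adaptiveness
        # gene of only w=1 codons
        assert cai("TCTTCT", model) == pytest.approx(1.0)
        # two codons with w=1 and w=w(TCA): geometric mean = sqrt(w)
        assert cai("TCTTCA", model) == pytest.approx(math.sqrt(w["TCA"]))
        # hand-computed three-codon fixture
        expected = (w["ATG"] * w["TCA"] * w["GGC"]) ** (1 / 3)
        assert cai("ATGTCAGGC", model) == pytest.approx(expected, abs=1e-12)

    def test_concatenation_invariance(self):
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 8 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"])
        gene = "ATGTCAGGCAAA"
        assert cai(gene + gene, model) == pytest.approx(cai(gene, model), abs=1e-12)

    @given(st.permutations(["ATG", "TCA", "GGC", "AAA", "TCT", "CGT"]))
    def test_permutation_invariance(self, codons):
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 8 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"])
        baseline = cai("ATGTCAGGCAAATCTCGT", model)
        assert cai("".join(codons), model) == pytest.approx(baseline, abs=1e-12)

    def test_monotone_under_worse_synonym(self):
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 8 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"])
        assert cai("ATGTCA", model) <= cai("ATGTCT", model)

    def test_zero_scorable_codons_errors(self):
        genome, genes = _genome_of_genes(["ATG" + "TCT" * 8 + "TAA"])
        model = build_cai_model(genes, genome, ["g0"])
        with pytest.raises(ValueError):
            cai("TAA", model)

    def test_empty_reference_errors(self):
        genome, genes = _genome_of_genes(["ATGTCTTAA"])
        with pytest.raises(ValueError):
            build_cai_model(genes, genome, [])
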
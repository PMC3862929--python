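import numpy as np
import pytest
from hypothesis import settings

from ribocodon import DensityTrack, Gene, Genome

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_genome():
    """One contig carrying a 12-nt plus-strand gene and its minus-strand twin."""
    # gene_plus: ATG TCA AGC TAA at 0..12; gene_minus: same CDS on -, at 20..32
    cds = "ATGTCAAGCTAA"
    rc = "TTAGCTTGACAT"
    seq = cds + "GGGGCCCC" + rc + "GGGG"
    genome = Genome({"c1": seq})
    gene_plus = Gene("gp", "c1", 0, 12, "+", "toy protein")
    gene_minus = Gene("gm", "c1", 20, 32, "-", "toy protein")
    return genome, gene_plus, gene_minus


def make_track(genome: Genome, plus=None, minus=None) -> DensityTrack:
    """DensityTrack with explicit per-position values (helpers for tests)."""
    track = DensityTrack.zeros(genome)
    contig = next(iter(genome.contigs))
    if plus is not None:
        track.data[contig]["+"][: len(plus)] = plus
    if minus is not None:
        track.data[contig]["-"][: len(minus)] = minus
    track.n_reads_assigned = track.total_mass()
    return track


@pytest.fixture
def track_builder():
    return make_track


@pytest.fixture
def uniform_track():
    def build(genome: Genome, value: float = 1.0) -> DensityTrack:
        track = DensityTrack.zeros(genome)
        for contig in track.data:
            for strand in track.data[contig]:
                track.data[contig][strand][:] = value
        track.n_reads_assigned = track.total_mass()
        return track

    return build
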
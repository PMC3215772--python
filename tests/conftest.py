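import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from isomap import (
    AlignmentRecord,
    GeneModel,
    Isochore,
    SimulationConfig,
)


@pytest.fixture
def toy_isochores():
    """Three contiguous isochores on one chromosome, one per GC regime."""
    return [
        Isochore("1 Mm1", "chr1", 0, 1_000_000, 34.0),  # L1
        Isochore("1 Mm2", "chr1", 1_000_000, 3_000_000, 44.0),  # H1
        Isochore("1 Mm3", "chr1", 3_000_000, 3_500_000, 55.0),  # H3
    ]


@pytest.fixture
def toy_genes():
    """Three genes: two in the H1 isochore (one pair overlapping), one in L1."""
    return [
        GeneModel("CCDS1.1", "chr1", "+", ((100_000, 100_600),), first_codon="ATG"),
        GeneModel(
            "CCDS2.1", "chr1", "+",
            ((1_200_000, 1_200_300), (1_250_000, 1_250_300)), first_codon="ATG",
        ),
        GeneModel("CCDS3.1", "chr1", "-", ((1_250_100, 1_250_700),), first_codon="ATG"),
    ]


@pytest.fixture
def small_config():
    """A config small enough for fast end-to-end runs."""
    return SimulationConfig(
        n_chromosomes=2,
        chromosome_length=10_000_000,
        total_reads_per_tissue=20_000,
        seed=42,
    )


def make_reads(positions, chrom="chr1", tissue="brain", length=25):
    return [AlignmentRecord(chrom, p, length, tissue) for p in positions]
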
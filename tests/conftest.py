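import pytest

from hml2quant.provirus_db import (
    GappedAlignment,
    ProvirusRecord,
    ProvirusSet,
    build_faux_genome,
)
from hml2quant.synthetic_data import SimConfig, simulate_family, simulate_genome


@pytest.fixture
def toy_set():
    """Three hand-written loci; B and C share a 20-nt block, A is distinct."""
    return ProvirusSet(
        [
            ProvirusRecord("locA", "ACGTACGTACGTACGTACGTTTTTCCCCGGGGAAAATTTT"),
            ProvirusRecord("locB", "GGGGCCCCAAAATTTTGGCCTTGGAACCTTGGAACCGGTT"),
            ProvirusRecord("locC", "TTGGAACCTTGGAACCGGTTACACACACACACACACACAC"),
        ]
    )


@pytest.fixture
def toy_alignment():
    """3 x 12 gapped alignment; rows ungap to known sequences."""
    return GappedAlignment(
        ["s1", "s2", "s3"],
        [
            "ACGT--ACGTAC",
            "ACGTTTACGTAC",
            "ACGTTTAC--AC",
        ],
    )


@pytest.fixture(scope="session")
def family20():
    """Default 20-locus family (8 young in sister pairs incl. tandem, 12 old)."""
    return simulate_family(SimConfig(), seed=42)


@pytest.fixture(scope="session")
def genome20(family20):
    return simulate_genome(family20, seed=43)


@pytest.fixture(scope="session")
def faux20(family20):
    genome, gtf = build_faux_genome(family20.proviruses, spacer_len=100)
    return genome, gtf
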
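import numpy as np
import pytest

from bridgecascade import CascadeConfig, default_genome, make_rng
from bridgecascade.genome import ChromosomeDecl, GenomeDeclaration


@pytest.fixture(scope="session")
def genome():
    """Default desk-scale three-chromosome genome."""
    return default_genome(seed=7)


@pytest.fixture(scope="session")
def small_genome():
    """Compact genome for sequence-heavy tests (TST parsing, homology)."""
    return GenomeDeclaration(
        [
            ChromosomeDecl("c1", 8_000_000, (3_500_000, 4_000_000)),
            ChromosomeDecl("c2", 6_000_000, (2_500_000, 3_000_000)),
            ChromosomeDecl("c3", 4_000_000, (100_000, 300_000), acrocentric=True),
        ],
        seed=5,
    )


@pytest.fixture(scope="session")
def toy_genome():
    """Single 1 Mb chromosome for base-resolution oracle comparisons."""
    return GenomeDeclaration(
        [ChromosomeDecl("t1", 1_000_000, (450_000, 500_000))], seed=11
    )


@pytest.fixture
def config():
    return CascadeConfig().validate()


@pytest.fixture
def rng():
    return make_rng(20240901)
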
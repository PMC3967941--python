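import numpy as np
import pytest

from popsel.association import GenotypeCounts
from popsel.haplotypes import HaplotypeMatrix


@pytest.fixture
def toy_t4() -> HaplotypeMatrix:
    """Four haplotypes, ten sites, derived counts (3, 2, 1) at the first three.

    The canonical worked example: S=3, unfolded SFS (1,1,1), pairwise-difference
    sum 10 over 6 pairs.
    """
    calls = np.array(
        [[0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
         [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
         [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
         [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]], dtype=np.int8)
    return HaplotypeMatrix(
        "T4", "1", np.arange(1, 11), [("A", "G")] * 10, calls,
        np.array(["p"] * 4, object))


@pytest.fixture
def table4_counts() -> tuple[GenotypeCounts, GenotypeCounts]:
    """rs13383830 genotype counts: 87 HESN and 436 controls."""
    return (GenotypeCounts("HESN", 3, 12, 72),
            GenotypeCounts("CTR", 2, 59, 375))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140213)
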
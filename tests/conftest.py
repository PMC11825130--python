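import numpy as np
import pytest

from sweepshare.scan import HaplotypeMatrix
from sweepshare.synth import Demography, simulate_neutral_haplotypes


@pytest.fixture(scope="session")
def demog() -> Demography:
    return Demography.constant(1e4)


@pytest.fixture(scope="session")
def neutral_hap_1mb(demog) -> HaplotypeMatrix:
    return simulate_neutral_haplotypes(demog, 20, 1_000_000, seed=42)


@pytest.fixture()
def random_hap() -> HaplotypeMatrix:
    """Small dense matrix with uniform random frequencies (not coalescent)."""
    rng = np.random.default_rng(7)
    n, S, L = 20, 400, 100_000
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=S, replace=False))
    counts = rng.integers(1, n, size=S)
    derived = np.zeros((n, S), dtype=np.int8)
    for j, c in enumerate(counts):
        derived[rng.choice(n, size=c, replace=False), j] = 1
    return HaplotypeMatrix(chrom="1", L=L, positions=positions, derived=derived)
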
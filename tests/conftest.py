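import numpy as np
import pytest

from breakmap.pipeline import simulate_case


def dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_case():
    """One full simulated discovery run at reduced scale, shared read-only."""
    return simulate_case(seed=11, chrom_len=200_000, window=20_000)
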
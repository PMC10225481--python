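import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oriseek.simulate import SimParams, simulate_genome


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-origin genome shared across tests (seed 7)."""
    return simulate_genome(SimParams(L=50_000, gene_len=900, igs_len=150, seed=7))


@pytest.fixture(scope="session")
def standard_sim():
    """Full-size study-condition genome (L=200 kb, GC skew 0.04, seed 1)."""
    return simulate_genome(SimParams(seed=1))
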
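import os

import numpy as np
import pytest

from termwin.coverage import CoverageTrack
from termwin.simulate import SimScenario, simulate

DATA = os.path.join(os.path.dirname(__file__), "data")


@pytest.fixture(scope="session")
def toy_gtf() -> str:
    return os.path.join(DATA, "toy5.gtf")


def random_track(rng: np.random.Generator, n: int = 20_000, strand: str = "+") -> CoverageTrack:
    """Small integer-valued track (values 0-5) for differential tests."""
    dense = rng.integers(0, 6, size=n).astype(float)
    # sprinkle zero stretches so gap closing and linking are exercised
    for _ in range(rng.integers(3, 8)):
        s = int(rng.integers(0, n - 1200))
        dense[s : s + int(rng.integers(50, 1200))] = 0.0
    return CoverageTrack.from_dense(strand, {"chrT": dense})


@pytest.fixture(scope="session")
def s1_result():
    """Scenario S1 (seed 1, 200 genes, defaults), shared across tests."""
    return simulate(SimScenario(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A fast, smaller world for unit-level pipeline tests."""
    return simulate(
        SimScenario(seed=7, n_contigs=1, contig_length_bp=600_000, n_genes=40)
    )
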
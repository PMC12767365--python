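import numpy as np
import pandas as pd
import pytest

from osmoloop.io import ContactMatrix, GenomeSpec, LoopSet
from osmoloop.simulate import SimParams


@pytest.fixture()
def genome() -> GenomeSpec:
    return GenomeSpec(("chrS",), (20_000_000,), 10_000)


@pytest.fixture()
def small_genome() -> GenomeSpec:
    return GenomeSpec(("chrS",), (500_000,), 10_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_matrix(genome, rng) -> ContactMatrix:
    """Sparse random contact matrix on 2000 bins."""
    n = 3_000
    b1 = rng.integers(0, genome.n_bins("chrS"), n)
    b2 = rng.integers(0, genome.n_bins("chrS"), n)
    c = rng.integers(1, 50, n)
    return ContactMatrix(genome, "chrS", b1, b2, c)


def make_loops(rows) -> LoopSet:
    df = pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )
    return LoopSet(df)


@pytest.fixture()
def small_params() -> SimParams:
    return SimParams(chrom_length=8_000_000, n_replicates=2, seed=99)
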
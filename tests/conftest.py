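import numpy as np
import pytest

from splicemark.coverage import CoverageTrack
from splicemark.simulate import generate_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome shared by read-only tests."""
    return generate_toy_genome(seed=7, n_genes=30)


@pytest.fixture()
def random_track():
    rng = np.random.default_rng(42)
    return CoverageTrack({"chr1": rng.uniform(0, 5, 10_000)}), rng


def constant_track(value: float, length: int = 10_000, chrom: str = "chr1"):
    return CoverageTrack({chrom: np.full(length, float(value))})
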
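import numpy as np
import pytest

from haplotile.pipeline import RunConfig, run_pipeline
from haplotile.synthetic_genome import DiploidChromosome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_diploid() -> DiploidChromosome:
    """A 500 kb diploid chromosome shared by read-only tests."""
    return DiploidChromosome.simulate(total_length=500_000, seed=11)


@pytest.fixture(scope="session")
def small_pipeline():
    """One full desk-scale pipeline run (reduced chromosome for speed)."""
    cfg = RunConfig(seed=5, total_length=800_000, max_path_span=200_000)
    return run_pipeline(cfg, with_pairs=True, with_overlap=False)
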
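import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One 3 Mb chromosome, two pools, full generator pipeline."""
    from regsel.synthetic_data import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(seed=42, chromosomes=(("chr1", 3_000_000),))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_sites(small_dataset):
    from regsel.genomic_io import call_substitutions

    return call_substitutions(small_dataset.genotypes,
                              small_dataset.outgroups, small_dataset.mask)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
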
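import numpy as np
import pytest

from ribofrag import GelModel
from ribofrag.pipeline import RunConfig, generate_dataset, run_pipeline


@pytest.fixture
def quiet_gel():
    """Default gel geometry without scanner noise (deterministic rendering)."""
    return GelModel(noise_sd=0.0)


@pytest.fixture
def clean_gel():
    """Noise-free, background-free gel for mass-conservation checks."""
    return GelModel(noise_sd=0.0, background=0.0)


@pytest.fixture
def ladder_sizes():
    return np.array([1000, 2000, 3000, 4000, 5000, 6000, 8000, 10000, 12000])


def exponential_fragments(rng, mean, n):
    """Integer fragment lengths, exponential with the given mean (>=1 nt)."""
    return np.maximum(1, np.rint(rng.exponential(mean, size=n))).astype(np.int64)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Seed-0 dataset at the standard study conditions, fully analysed."""
    cfg = RunConfig(seed=0)
    data_dir = tmp_path_factory.mktemp("default_dataset")
    generate_dataset(cfg, data_dir)
    report = run_pipeline(data_dir)
    return cfg, data_dir, report
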
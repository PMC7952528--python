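import numpy as np
import pytest

from ohnokit import pipeline
from ohnokit.config import SimConfig


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """The study conditions: default simulator settings, fixed seed."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(default_config):
    return pipeline.simulate_bundle(default_config)


@pytest.fixture(scope="session")
def called_pairs(bundle):
    high_conf = pipeline.run_homology(bundle)
    return pipeline.run_ohnolog_calling(bundle, high_conf)


@pytest.fixture(scope="session")
def divergence_reports(bundle, called_pairs):
    reports, stats = pipeline.run_divergence(bundle, called_pairs)
    return reports, stats


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
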
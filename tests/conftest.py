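import numpy as np
import pytest

from pitchnav import AnalysisConfig, GeneratorParams, analyze_repeats, simulate_dataset


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """~1,200 synthetic bouts over 2 repeats (session-wide workhorse)."""
    return simulate_dataset(GeneratorParams(), n_repeats=2, bouts_per_repeat=600, seed=11)


@pytest.fixture(scope="session")
def small_analysis(small_dataset, config):
    return analyze_repeats(
        [trace for trace, _ in small_dataset.repeats], small_dataset.metadata(), config
    )


@pytest.fixture(scope="session")
def dataset10k():
    """The parameter-recovery corpus: 10,000 bouts over 5 repeats."""
    return simulate_dataset(GeneratorParams(), n_repeats=5, bouts_per_repeat=2000, seed=1)


@pytest.fixture(scope="session")
def analysis10k(dataset10k, config):
    return analyze_repeats(
        [trace for trace, _ in dataset10k.repeats], dataset10k.metadata(), config
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
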
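import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from thermocontrast import (
    GenerativeConfig,
    innocuous_model_table,
    prepare_analysis_table,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    return GenerativeConfig(n_participants=24, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, include_traces=True)


@pytest.fixture(scope="session")
def medium_dataset():
    # larger cohort for model fits; no traces needed
    return simulate_dataset(GenerativeConfig(n_participants=120, seed=7))


@pytest.fixture(scope="session")
def analysis_tables(medium_dataset):
    analysis, summary, exclusions = prepare_analysis_table(
        medium_dataset.trials, medium_dataset.participants
    )
    return analysis, summary, exclusions


@pytest.fixture(scope="session")
def model_table(medium_dataset, analysis_tables):
    analysis, summary, _ = analysis_tables
    return innocuous_model_table(analysis, summary, medium_dataset.participants)


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
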
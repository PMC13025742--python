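import numpy as np
import pytest

from actscreen import (
    ModelSpec,
    PreprocessConfig,
    SimulationConfig,
    build_sample_table,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact labeled cohort shared by classifier and pipeline tests."""
    return simulate_cohort(8, 6, 3, 0, samples_per_participant_range=(3, 4),
                           seed=123)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_sample_table(small_cohort, PreprocessConfig())


@pytest.fixture
def clean_exo_config():
    """Zero-noise, fully valid exotropic recording configuration."""
    return SimulationConfig(
        condition="exotropia", deviation_amplitude=0.1,
        noise_sd=0.0, invalid_frame_prob=0.0,
    )


@pytest.fixture
def rf_point_spec():
    """Single-candidate random forest spec for fast deterministic fits."""
    return ModelSpec("random_forest", {
        "n_estimators": [100], "max_depth": [20],
        "min_samples_split": [5], "criterion": ["gini"],
    })
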
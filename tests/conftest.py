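import numpy as np
import pandas as pd
import pytest

from phosphostrat import OmicsMatrix, SimulationConfig, simulate_cohort
from phosphostrat.simulate import simulate_screen


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact cohort: full group structure, fewer features, fast to analyse."""
    return SimulationConfig(
        n_features=500,
        n_signature_features=18,
        n_kinases=10,
        substrates_per_kinase=10,
        n_drugs=8,
        planted_sensitive_drugs=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def noiseless_screen_cohort():
    """Cohort plus a zero-noise screen for exact dose-response checks."""
    cfg = SimulationConfig(
        n_features=200,
        n_signature_features=10,
        n_kinases=5,
        substrates_per_kinase=10,
        n_drugs=8,
        planted_sensitive_drugs=3,
        screen_noise_cv=0.0,
        ic50_sample_sd=0.0,
        missing_rate=0.0,
        seed=7,
    )
    cohort = simulate_cohort(cfg)
    screen = simulate_screen(cfg, cohort.metadata)
    return cohort, screen


def toy_matrix(values: np.ndarray, feature_ids=None, sample_ids=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))
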
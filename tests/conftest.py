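import logging

import pytest

from srsradiomics import ForestConfig, SyntheticConfig, generate_cohorts

logging.getLogger("srsradiomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohorts():
    """Two-center cohorts under the default (realistic batch-effect) regime."""
    return generate_cohorts(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_grid():
    """Single-cell hyperparameter grid for fast experiment-driver tests."""
    return ForestConfig(n_estimators_grid=(100,), max_features_grid=("sqrt",),
                        min_samples_leaf_grid=(3,))


@pytest.fixture(scope="session")
def shared_law_config():
    """Both centers drawn from one generative law (no batch effects, same
    clinical profile, equal sizes)."""
    from srsradiomics.cohort import DEFAULT_CLINICAL_PROFILES

    profiles = {"A": DEFAULT_CLINICAL_PROFILES["A"],
                "B": DEFAULT_CLINICAL_PROFILES["A"]}

    def make(seed: int, **overrides) -> SyntheticConfig:
        kwargs = dict(seed=seed, n_bms_per_center=(123, 123),
                      n_patients_per_center=(99, 99),
                      prevalence_per_center=(0.2, 0.2),
                      batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0),
                      clinical_profiles=profiles)
        kwargs.update(overrides)
        return SyntheticConfig(**kwargs)

    return make
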
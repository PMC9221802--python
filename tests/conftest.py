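import numpy as np
import pytest

from rtae.synthetic_cohort import SyntheticCohortConfig, generate_feature_table


@pytest.fixture(scope="session")
def planted_cohort():
    """n=300 cohort with one strong planted feature (delta=2) among 100
    correlated noise radiomics features; CR prevalence 0.3."""
    cfg = SyntheticCohortConfig(
        n_patients=300,
        n_radiomics=100,
        prevalence=0.3,
        planted_features=[(0, 2.0)],
        seed=11,
    )
    return generate_feature_table(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Published-scale cohort: 51 patients, 854 features, CR prevalence 14/51."""
    cfg = SyntheticCohortConfig(seed=7)
    return generate_feature_table(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
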
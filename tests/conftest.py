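import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seroarray import normalize, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**kw) -> synthetic.SimConfig:
    """A fast 40-antigen, 4-patient cohort preset for unit tests."""
    base = dict(
        n_antigens=40,
        n_patients=4,
        group_sizes=(2, 2),
        n_pl_higher=4,
        n_sf_higher=1,
        n_similar=2,
        # planted effects on 5/40 antigens leave no room for the full-scale
        # correlations, so the small preset targets looser ones
        duplicate_rho=0.95,
        fluid_rho=0.85,
        seed=7,
    )
    base.update(kw)
    return synthetic.SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return synthetic.generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    normalized, cohort = normalize.normalize_cohort(
        small_sim.arrays, small_sim.design, small_sim.meta
    )
    return normalized, cohort


@pytest.fixture(scope="session")
def study_sim():
    """One full-size cohort at the default study-condition preset."""
    return synthetic.generate_cohort(synthetic.study_preset(seed=1))


@pytest.fixture(scope="session")
def study_cohort(study_sim):
    normalized, cohort = normalize.normalize_cohort(
        study_sim.arrays, study_sim.design, study_sim.meta
    )
    return normalized, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20120417)
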
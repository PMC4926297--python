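import pytest
from hypothesis import HealthCheck, settings

from metadriver.synthetic_cohort import SimulationParams, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down cohort design used across the unit tests."""
    return SimulationParams(
        n_cancers=2,
        n_tumour=60,
        n_normal=20,
        n_genes=200,
        n_chromosomes=4,
        n_planted_drivers=8,
        n_signature_genes=10,
        n_hypoxia_coupled_drivers=4,
        n_prognostic_genes=2,
        metabolic_fraction=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params, 0)
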
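import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from proteonoise import (
    ControlNormalizer,
    SimulationConfig,
    assemble_matrix,
    simulate_cohorts,
    simulate_study,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def normalize_to_matrix(samples, reference_pos_level=None):
    norm = ControlNormalizer(reference_pos_level=reference_pos_level)
    return assemble_matrix(norm.fit(samples).transform(samples))


@pytest.fixture(scope="session")
def small_config():
    """A fast study: 40 analytes, 4 planted noise reporters, 10 planted shifts."""
    return SimulationConfig(
        n_analytes=40,
        noise_set=("P001", "P002", "P003", "P004"),
        level_shift_set=tuple(f"P{i:03d}" for i in range(5, 15)),
        n_per_cohort={"young": 10, "middle": 6, "old": 10, "disease": 8, "tpe": 6},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    samples, truth = simulate_study(small_config)
    return normalize_to_matrix(samples), truth


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    samples, truth = simulate_cohorts(small_config)
    return normalize_to_matrix(samples), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
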
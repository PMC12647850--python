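import numpy as np
import pytest
from hypothesis import settings

from triadscan import ComponentSpec, ProfileSimSpec, generate_profiles

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

PX = 0.067


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-condition cohort with ground truth (seeded)."""
    spec = ProfileSimSpec(n_chromosomes=30, seed=11)
    return generate_profiles(spec)


@pytest.fixture(scope="session")
def short_only_cohort():
    """Shorter-component-only cohort, as in the spectral-recipe analyses."""
    spec = ProfileSimSpec(
        n_chromosomes=40, seed=11, long_component=ComponentSpec(present=False)
    )
    return generate_profiles(spec)


@pytest.fixture
def grid():
    return np.arange(64) * PX


def gaussian(grid, center, sigma, height=1.0):
    return height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
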
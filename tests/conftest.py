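import numpy as np
import pytest

from bpmeth import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Shared mid-size cohort with two planted regions and a mediated path."""
    return synthetic.generate_cohort(n_subjects=120, n_probes=1200, seed=42)


@pytest.fixture(scope="session")
def reference_profiles():
    return synthetic.generate_reference_profiles(600, 50, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
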
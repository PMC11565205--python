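import hypothesis
import numpy as np
import pytest

import sorghum_iwue as si

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_trial():
    """One full-size synthetic trial (89 genotypes x 2 treatments x 3 reps)."""
    return si.simulate_trial(si.SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def derived(default_trial):
    records, _ = default_trial
    return si.derive_traits(records)


@pytest.fixture(scope="session")
def retained_means(derived):
    means = si.aggregate_means(derived)
    retained, _ = si.apply_exclusion_filter(means)
    return retained


@pytest.fixture(scope="session")
def fitted_curve(retained_means):
    return si.fit_reference_curve(retained_means["g_s"], retained_means["iwue"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
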
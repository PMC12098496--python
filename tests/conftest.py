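import numpy as np
import pytest

from gradstates import CohortSpec, generate_cohort, sliding_window_fc


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared across tests (8 subjects, 12 regions)."""
    spec = CohortSpec(n_patients=4, n_controls=4, T=150, P=12, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_stacks(small_cohort):
    return [sliding_window_fc(s, window_length=50, step=1)
            for s in small_cohort.subjects]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
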
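import numpy as np
import pytest

from cvarlearn import task


@pytest.fixture(scope="session")
def block_specs():
    return task.default_block_specs()


@pytest.fixture(scope="session")
def small_cvar_cohort():
    """Six CVaR agents with a planted negative eta-trait link."""
    spec = task.CohortSpec(n_agents=6, model="cvar", seed=11)
    return task.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
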
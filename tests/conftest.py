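import numpy as np
import pytest

from gammarep import GeneratorConfig, simulate_cohort
from gammarep.dynamics import single_trial_table


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size spectrum-level cohort under the study conditions."""
    return simulate_cohort(GeneratorConfig(), mode="spectra",
                           include_ecg=False, seed=1)


@pytest.fixture(scope="session")
def default_trial_table(default_cohort):
    return single_trial_table(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_config(**kw):
    """Small cohort config that still covers the 137-trial block."""
    base = dict(n_vss=3, n_control=3, n_trials_per_condition=28)
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture()
def tiny_cfg():
    return tiny_config()
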
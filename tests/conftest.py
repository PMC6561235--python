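import numpy as np
import pytest

import webforage as wf
from webforage.framing import study_frame


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated cohort shared across tests (8 subjects)."""
    pop = wf.PopulationConfig(n_subjects=8)
    return wf.simulate_study(pop, seed=7)


@pytest.fixture(scope="session")
def small_thresholds(small_study):
    return wf.compute_thresholds(small_study)


@pytest.fixture(scope="session")
def small_frame(small_study, small_thresholds):
    return study_frame(small_study.sessions, small_thresholds)


def make_agent(**overrides):
    """One deterministic agent with hand-set parameters for unit tests."""
    defaults = dict(
        subject_id="t000",
        tau=np.array([15.0, 15.0, 15.0, 15.0]),
        beta=0.5,
        gamma0=-0.6,
        gamma_E=0.0,
        E=0.0,
        eta=0.0,
        rating_mu=np.zeros(4),
        rating_a=0.02,
        rating_b=0.3,
        rating_c=0.0,
        sigma_r=1.0,
        cutpoints=np.array([-1.2, 0.0, 1.2]),
        alpha0=float(np.log(1.5)),
        delta=0.15,
        sigma_rt=0.35,
        logk_delay=-5.26,
        logk_prob=0.28,
        choice_sharpness=3.0,
    )
    defaults.update(overrides)
    return wf.AgentParams(**defaults)
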
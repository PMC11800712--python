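import numpy as np
import pytest

from ivsurvsim import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_cohort(z, cm, cu, x, time, event, tau_max=5.0):
    to = lambda a: np.asarray(a, float)
    return Cohort(
        z=to(z), cm=to(cm), cu=to(cu), x=to(x),
        time=to(time), event=np.asarray(event, int), tau_max=tau_max,
    )


@pytest.fixture
def simple_cohort():
    """Small deterministic cohort with events at distinct times."""
    n = 8
    return make_cohort(
        z=[0, 0, 0, 0, 1, 1, 1, 1],
        cm=[-0.5, 0.3, 1.2, -1.0, 0.1, -0.2, 0.8, -0.7],
        cu=np.zeros(n),
        x=[0, 0, 0, 1, 0, 1, 1, 1],
        time=[1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5],
        event=[1, 1, 1, 1, 1, 1, 1, 1],
    )
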
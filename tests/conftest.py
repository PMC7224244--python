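"""Shared fixtures.

The expensive objects (the 1000-point front problem and its continued
branch, the 2D bump) are session-scoped: they are computed once and shared
between the unit tests and the acceptance checks.
"""

import numpy as np
import pytest

from neurocont import bump2d, front1d
from neurocont.continuation import ContinuationSettings


@pytest.fixture(scope="session")
def front_problem():
    return front1d.FrontProblem()  # domain [0, 50], N = 1000, beta = 20


@pytest.fixture(scope="session")
def front_initial(front_problem):
    """Converged front at h = 0.3 (time-stepped then Newton-polished)."""
    return front1d.initial_front(front_problem)


@pytest.fixture(scope="session")
def front_branch_up(front_problem, front_initial):
    """Front branch continued from h = 0.3 towards increasing h, through the
    speed reversal at h = 1/2 and around the upper fold."""
    settings = ContinuationSettings(ds=0.3, max_steps=45, newton_tol=1e-9,
                                    adapt_step=True, ds_max=0.6)
    return front1d.continue_front_in_h(front_problem, front_initial, settings)


@pytest.fixture(scope="session")
def front_branch_down(front_problem, front_initial):
    """Front branch continued towards decreasing h, around the lower fold."""
    settings = ContinuationSettings(ds=0.3, max_steps=40, newton_tol=1e-9,
                                    adapt_step=True, ds_max=0.6, direction=-1)
    return front1d.continue_front_in_h(front_problem, front_initial, settings)


@pytest.fixture(scope="session")
def front_speeds(front_problem, front_initial):
    """Speeds at the fixed thresholds used by the symmetry and cross-method
    checks, from natural continuation off the h = 0.3 front."""
    out = {}
    for h in (0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7):
        out[h] = front1d.solve_front_at_h(front_problem, h, front_initial,
                                          h_seed=0.3).speed
    return out


@pytest.fixture(scope="session")
def bump2d_problem():
    return bump2d.Problem2D(N=64)


@pytest.fixture(scope="session")
def bump2d_state(bump2d_problem):
    """Converged travelling bump at the reference parameters (A = 2)."""
    return bump2d.initial_bump_2d(bump2d_problem, T=80.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140725)
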
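import numpy as np
import pytest

from drinksmoke import (
    DEFAULT_INITIAL_STATE,
    ObjectiveWeights,
    forward_backward_sweep,
    simulate,
    table2_preset,
)


@pytest.fixture(scope="session")
def table2():
    return table2_preset()


@pytest.fixture(scope="session")
def initial_state():
    return np.array(DEFAULT_INITIAL_STATE)


@pytest.fixture(scope="session")
def baseline_oc_solution(table2, initial_state):
    """The converged optimal-control run of the baseline 52-week scenario
    (A = 100, w = 0.5, step 0.01, all five controls enabled).  Session-scoped:
    the sweep is the most expensive computation in the suite and several
    checks read different aspects of the same solution."""
    return forward_backward_sweep(
        table2, initial_state, ObjectiveWeights(), t1=52.0, step=0.01
    )


@pytest.fixture(scope="session")
def baseline_uncontrolled(table2, initial_state):
    """Matching no-control trajectory on the same grid."""
    return simulate(table2, initial_state, 52.0, step=0.01)
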
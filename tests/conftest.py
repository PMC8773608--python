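import numpy as np
import pytest

import magcomp as m


@pytest.fixture(scope="session")
def duration_set():
    return m.duration_stimulus_set()


@pytest.fixture(scope="session")
def numerosity_set():
    return m.numerosity_stimulus_set()


@pytest.fixture(scope="session")
def duration_plan():
    return m.build_session_plan("duration_while", n_blocks=2)


@pytest.fixture(scope="session")
def run_observer():
    """Duration observer with the running-dilation gain (PSE 513 ms)."""
    return m.duration_observer_params()


@pytest.fixture(scope="session")
def cohort_trials(duration_plan, run_observer):
    """One simulated 15-participant while-running session (study counts)."""
    return m.simulate_cohort(
        duration_plan, m.CohortParams(n_participants=15, seed=42), run_observer
    )


@pytest.fixture(scope="session")
def paper_levels():
    return np.array([284, 342, 413, 498, 600, 723, 872, 1052, 1268], dtype=float)
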
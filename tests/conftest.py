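"""Shared fixtures: parameter sets and (expensive) steady-state cycles.

Steady-state pacing runs are session-scoped because they are the costly
ingredient of the acceptance checks; every test that needs the control
cycle shares one run.  The shipped parameter file's initial block is the
5 Hz control steady state, so control runs converge in a few beats while
intervention runs re-equilibrate from there.
"""

import pytest

import dyadca as d
from dyadca.engine import SolverSettings, pace_to_steady_state


#: desk-scale pacing caps (beats), chosen to re-equilibrate interventions
#: from the shipped control steady state
CAP_5HZ = 150
CAP_1HZ = 80
CRITERION = 1.0e-4


@pytest.fixture(scope="session")
def params():
    return d.ModelParameters.default()


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


def run_steady(params, dist=d.CONTROL, buffer=d.NONE, freq=5.0,
               max_beats=None, dialysis=None):
    """Pace to (quasi-)steady state at desk scale; returns the final cycle."""
    if dialysis is None:
        dialysis = buffer.enabled
    protocol = d.make_current_clamp(freq, 600.0, dialysis=dialysis)
    cap = max_beats or (CAP_5HZ if freq >= 2 else CAP_1HZ)
    res = pace_to_steady_state(params, dist, buffer, protocol,
                               SolverSettings(), criterion=CRITERION,
                               max_beats=cap)
    return res


@pytest.fixture(scope="session")
def control_5hz(params):
    return run_steady(params)


@pytest.fixture(scope="session")
def control_metrics(control_5hz):
    return d.cycle_metrics(control_5hz.cycle)


@pytest.fixture(scope="session")
def control_1hz(params):
    return run_steady(params, freq=1.0, dialysis=True)


@pytest.fixture(scope="session")
def egta10_1hz(params):
    return run_steady(params, buffer=d.egta(10.0), freq=1.0)


@pytest.fixture(scope="session")
def bapta10_1hz(params):
    return run_steady(params, buffer=d.bapta(10.0), freq=1.0)
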
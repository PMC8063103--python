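"""Shared fixtures: expensive paced simulations are session-scoped."""

import numpy as np
import pytest

from atriawave.model import baseline_parameters
from atriawave.simulator import PacingProtocol, SolverSettings, run_paced

#: protocol used by the shared control run: 30 pre-pacing beats to approach
#: the periodic steady state, last 10 recorded at 1 Hz
CONTROL_PROTOCOL = PacingProtocol(n_beats=40, record_last_n_beats=10)
SOLVER = SolverSettings(dt=0.05)


@pytest.fixture(scope="session")
def control_result():
    """Baseline model paced to (near) steady state; reused across tests."""
    res = run_paced(baseline_parameters(), CONTROL_PROTOCOL, solver=SOLVER)
    assert not res.failed
    return res


@pytest.fixture(scope="session")
def short_result():
    """A cheap 5-beat run for structural checks."""
    prot = PacingProtocol(n_beats=5, record_last_n_beats=5)
    return run_paced(baseline_parameters(), prot, solver=SOLVER)
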
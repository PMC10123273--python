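"""Shared fixtures: baseline model runs and a session-wide simulation cache.

Long paced simulations dominate the suite's runtime, so anything reusable
(the default 120 s baseline trace, insult-level windows) is computed once per
session and shared through a single in-memory cache.
"""

import numpy as np
import pytest

from txcardio.insults import SimulationCache
from txcardio.model import PacingProtocol, ParameterSet, SimTrace, simulate


@pytest.fixture(scope="session")
def baseline_params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def default_protocol() -> PacingProtocol:
    return PacingProtocol()


@pytest.fixture(scope="session")
def sim_cache() -> SimulationCache:
    return SimulationCache()


@pytest.fixture(scope="session")
def baseline_trace(baseline_params, default_protocol) -> SimTrace:
    """Full 120 s / 1 Hz run of the unscaled model (states retained)."""
    return simulate(baseline_params, default_protocol)


def make_trace(time, V, Cai=None, SL=None, stim_times=(0.0,), pacing_rate=1.0,
               currents=None):
    """Construct a SimTrace from explicit waveforms (for metric oracles)."""
    from txcardio.model import CURRENT_NAMES

    time = np.asarray(time, dtype=float)
    V = np.asarray(V, dtype=float)
    n = time.size
    cur = {name: np.zeros(n) for name in CURRENT_NAMES}
    if currents:
        for k, v in currents.items():
            cur[k] = np.asarray(v, dtype=float)
    return SimTrace(
        time=time,
        V=V,
        Cai=np.zeros(n) if Cai is None else np.asarray(Cai, dtype=float),
        SL=np.full(n, 1.9) if SL is None else np.asarray(SL, dtype=float),
        currents=cur,
        stimulus_times=np.asarray(stim_times, dtype=float),
        pacing_rate=pacing_rate,
    )
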
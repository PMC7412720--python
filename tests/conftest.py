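import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from odorspike import (
    AnalysisWindows,
    CellRecord,
    EventTable,
    Session,
    SimConfig,
    SpikeTrain,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_events():
    """Three odors x two trials on the standard 2 s / 28 s schedule."""
    rows = []
    t = 30.0
    for block in range(2):
        for odor, veh in [("odorA", False), ("odorB", False), ("oil", True)]:
            rows.append(
                {"odor_id": odor, "is_vehicle": veh, "onset_s": t, "offset_s": t + 2.0}
            )
            t += 30.0
    return EventTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_session(simple_events, rng):
    """Two-cell session with Poisson spiking, no respiration."""
    duration = float(simple_events.df["offset_s"].iloc[-1] + 28.0)
    cells = []
    for i, (region, rate) in enumerate([("DTT", 3.0), ("AON", 5.0)]):
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0, duration - 1e-6, size=n))
        times = np.unique(times)
        rec = CellRecord(f"c{i}", region, "subj1", "F")
        cells.append((rec, SpikeTrain(f"c{i}", times)))
    return Session(
        cells=tuple(cells),
        events=simple_events,
        duration_s=duration,
        session_id="tiny",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort with respiration, reused across tests."""
    config = SimConfig(
        n_cells={"DTT": 4, "AON": 4},
        n_odorants=4,
        n_trials=8,
        seed=7,
    )
    sessions, truth = simulate_cohort(config)
    return config, sessions, truth
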
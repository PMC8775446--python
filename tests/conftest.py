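import numpy as np
import pytest

import placefield as plf


@pytest.fixture(scope="session")
def geometry():
    return plf.TrackGeometry()


@pytest.fixture(scope="session")
def slow_profile():
    return plf.SENSOR_PROFILES["gcamp6s"]


@pytest.fixture(scope="session")
def short_trajectory(geometry):
    """2-minute deterministic trajectory with reversals, 20 fps."""
    return plf.simulate_trajectory(geometry, duration=120.0, fps=20.0,
                                   mean_speed=3.0, turn_prob=0.2, seed=42)


@pytest.fixture(scope="session")
def small_session(geometry):
    """20 high-contrast tuned cells (10:0.1 events/s), full 15-min session."""
    cells = plf.tile_place_cells(20, in_field_rate=10.0, out_field_rate=0.1,
                                 seed=1)
    return plf.make_session(cells, geometry=geometry, duration=900.0,
                            snr=10.0, seed=7)


def events_by_cell(events):
    out = {}
    for e in events:
        out.setdefault(e.cell_id, []).append(e)
    return out
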
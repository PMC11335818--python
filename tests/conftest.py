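import numpy as np
import pytest

from headgaze import pipeline
from headgaze.simulate import SimConfig, simulate_session

FULL_SEED = 11


@pytest.fixture(scope="session")
def full_session():
    """Default-config synthetic session (6 conditions x 45 shifts)."""
    return simulate_session(SimConfig(seed=FULL_SEED))


@pytest.fixture(scope="session")
def full_processed(full_session):
    s = full_session
    return pipeline.process_session(s.marker, s.eye, s.annotations,
                                    s.ceiling_camera, s.scene_camera,
                                    s.marker_model)


@pytest.fixture(scope="session")
def small_session():
    """Cheap session for structural tests: 3 shifts per condition."""
    return simulate_session(SimConfig(seed=5, shifts_per_condition=3))


@pytest.fixture(scope="session")
def small_processed(small_session):
    s = small_session
    return pipeline.process_session(s.marker, s.eye, s.annotations,
                                    s.ceiling_camera, s.scene_camera,
                                    s.marker_model)


def matched_events(truth_df, detected):
    """Pair truth and detected events by onset order; requires equal counts."""
    tr = truth_df.sort_values("saccade_onset").reset_index(drop=True)
    det = sorted(detected, key=lambda e: e.saccade_onset)
    assert len(det) == len(tr)
    return tr, det
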
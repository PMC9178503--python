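"""Shared fixtures: a standard gain-manipulation session with ground truth."""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

import gaintrack as gt

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

# field centers sit away from the lap boundary so that per-lap sweep
# labeling is unambiguous
CELL_CENTERS = (36.0, 108.0, 180.0, 252.0, 324.0)


@pytest.fixture(scope="session")
def standard_profile():
    """40-lap session: 10 baseline laps, 10 ramp laps, 15 hold, 5 dark."""
    return gt.GainProfile(epoch_laps=(10, 10, 15, 5), final_gain=1.5)


@pytest.fixture(scope="session")
def standard_session(standard_profile):
    """Five noiseless landmark-locked cells (peak 15 Hz, width 40 deg)."""
    specs = {
        k: gt.PlaceCellSpec(
            frame="landmark",
            center=c,
            width=40.0,
            peak_rate=15.0,
            baseline_rate=0.0,
        )
        for k, c in enumerate(CELL_CENTERS)
    }
    return gt.simulate_session(
        behavior=gt.BehaviorConfig(session_laps=40, seed=11),
        profile=standard_profile,
        cell_specs=specs,
        seed=11,
    )


@pytest.fixture(scope="session")
def standard_fields(standard_session):
    """Detected fields for every unit of the standard session."""
    return gt.detect_session_fields(standard_session)


def frame_laps_run(session):
    """Number of cue-frame laps at least partially traversed."""
    fp = session.frame_position(session.profile.cue)
    return int(np.ceil(fp.angle_unwrapped[-1] / 360.0))
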
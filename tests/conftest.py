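import numpy as np
import pytest

from curtainkit import (AcquisitionConfig, DnaTether, MotorParams,
                        simulate_motor_path, render_stack)


@pytest.fixture
def acq_short():
    return AcquisitionConfig(n_frames=200, image_shape=(64, 128))


@pytest.fixture
def tether():
    return DnaTether()


@pytest.fixture
def mover_track(acq_short, tether):
    params = MotorParams(initial_position_bp=2000.0, velocity_bp_s=18.0)
    return simulate_motor_path(params, acq_short, tether, seed=11)


def make_trajectory(times, positions, molecule_id=0):
    """Build a calibrated Trajectory directly from (t, bp) arrays."""
    from curtainkit.track import Trajectory
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    frames = np.round(times / max(times[1] - times[0], 1e-9)).astype(int)
    frames = np.arange(len(times)) if len(np.unique(frames)) != len(frames) else frames
    t = Trajectory(molecule_id=molecule_id, channel=0, frames=frames,
                   times_s=times, x_px=positions / 485.02,
                   y_px=np.zeros_like(times))
    t.position_bp = positions
    return t
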
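import numpy as np
import pytest

from parkscreen import KinematicTrial


def make_trial(
    series,
    task="finger_tapping",
    hand="non_dominant",
    trial_index=1,
    sample_rate_hz=64.0,
    participant_id="P001",
    **channel_overrides,
):
    """Build a trial whose task-relevant axis carries ``series``; other
    channels default to zeros of matching length."""
    series = np.asarray(series, dtype=float)
    axis = {"finger_tapping": "gyro_x", "hand_rotation": "gyro_y"}.get(task, "gyro_x")
    channels = {
        c: np.zeros_like(series)
        for c in ("gyro_x", "gyro_y", "gyro_z", "accel_x", "accel_y", "accel_z")
    }
    channels[axis] = series
    channels.update(
        {k: np.asarray(v, dtype=float) for k, v in channel_overrides.items()}
    )
    return KinematicTrial(
        participant_id=participant_id,
        hand=hand,
        task=task,
        trial_index=trial_index,
        sample_rate_hz=sample_rate_hz,
        **channels,
    )


def sinusoid(amplitude, frequency_hz, duration_s=12.0, sample_rate_hz=64.0, phase=0.0):
    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    return amplitude * np.sin(2 * np.pi * frequency_hz * t + phase)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
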
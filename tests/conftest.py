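import numpy as np
import pytest

import tetherforce as tf


@pytest.fixture
def quiet_config():
    """Noiseless, event-free generator settings."""
    return tf.SimConfig(
        seed=0,
        deflection_noise_sd=0.0,
        event_rate_short=0.0,
        event_rate_long=0.0,
        r_event_prob=0.0,
        f_event_prob=0.0,
        complex_prob=0.0,
        tirf_shot_noise=False,
    )


@pytest.fixture(scope="session")
def default_run():
    """One default-condition simulated recording, analyzed end to end."""
    cfg = tf.SimConfig(seed=3)
    rec, gt = tf.simulate_recording(cfg)
    segments, events, by_seg = tf.analyze_recording(rec)
    return cfg, rec, gt, segments, events, by_seg


def make_recording_constant_z(z_nm: float, duration: float = 2.0, frame_rate: float = 10.0):
    """Minimal recording with the servo parked at a fixed height."""
    times = np.arange(0.0, duration, 0.01)
    fnum = np.floor(times * frame_rate) / 1000.0
    return tf.Recording(
        times=times,
        v_defl=np.zeros_like(times),
        z_servo=np.full_like(times, z_nm),
        fnum=fnum,
        meta={"z_contact": 0.0, "seed": 0, "frame_rate": frame_rate},
    )
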
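import dataclasses

import numpy as np
import pytest

from opmtools.core import ChannelInfo, Recording
from opmtools.forward import build_array_geometry, default_reference_channels
from opmtools.synth import AEFConfig, InterferenceSpec, TappingConfig, simulate_evoked_session


def make_recording(n_channels=4, n_samples=500, fs=250.0, seed=0, with_trigger=False):
    """Small random recording with valid scalp-channel geometry."""
    rng = np.random.default_rng(seed)
    geom = build_array_geometry(max(4, n_channels), "dual")
    channels = list(geom.channels[:n_channels])
    if with_trigger:
        channels.append(ChannelInfo("TRIG", "trigger"))
    data = 1e-12 * rng.standard_normal((len(channels), n_samples))
    if with_trigger:
        data[-1] = 0.0
    return Recording(channels, data, fs)


@pytest.fixture(scope="session")
def small_geom():
    return build_array_geometry(12, "dual")


@pytest.fixture(scope="session")
def reference_channels():
    return default_reference_channels()


@pytest.fixture(scope="session")
def aef_session_small():
    """A short mobile evoked session: 40 tones, full interference mix."""
    cfg = dataclasses.replace(AEFConfig(), n_trials=40, still_until=5.0)
    return simulate_evoked_session(cfg, seed=7)


@pytest.fixture(scope="session")
def quiet_aef_session():
    """Interference-free, motion-free evoked session (brain + trigger only)."""
    spec = InterferenceSpec(homogeneous_peak=0.0, static_field=0.0, gradient_scale=0.0,
                            lines=(), sensor_noise_asd=0.0)
    cfg = dataclasses.replace(AEFConfig(), n_trials=20, still_until=2.0,
                              translation_range=0.0, rotation_range=0.0, interference=spec)
    return simulate_evoked_session(cfg, seed=3)
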
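"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from entrain.core_io import Event, Recording
from entrain.protocol import schedule_session
from entrain.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_schedule():
    """1 block per condition, 6 bursts of 20 pulses at 10 Hz."""
    return schedule_session(10.0, n_blocks_per_condition=1, bursts_per_block=6,
                            n_pulses=20, seed=11)


@pytest.fixture(scope="session")
def clean_cfg():
    """Artifact-free, strongly entrained config at a small scale."""
    return SynthConfig(n_channels=16, fs=500.0, iaf=10.0, entrain_strength=10.0,
                       ringing_amp=0.0, decay_amp=0.0, blink_rate=0.0, seed=21)


@pytest.fixture(scope="session")
def artifact_cfg():
    return SynthConfig(n_channels=16, fs=500.0, iaf=10.0, entrain_strength=10.0,
                       ringing_amp=600.0, decay_amp=40.0, blink_rate=4.0, seed=22)


@pytest.fixture(scope="session")
def clean_session(clean_cfg, small_schedule):
    return generate_session(clean_cfg, small_schedule)


@pytest.fixture(scope="session")
def artifact_session(artifact_cfg, small_schedule):
    return generate_session(artifact_cfg, small_schedule)


@pytest.fixture
def tiny_recording():
    """2-channel 1 s recording with a couple of events."""
    fs = 500.0
    t = np.arange(int(fs)) / fs
    data = np.vstack([50 * np.sin(2 * np.pi * 10 * t),
                      20 * np.cos(2 * np.pi * 7 * t)])
    events = [Event(0.1, "burst_onset", "rhythmic", 0),
              Event(0.1, "pulse", "rhythmic", 0),
              Event(0.2, "pulse", "rhythmic", 0),
              Event(0.2, "burst_offset", "rhythmic", 0)]
    return Recording(data, fs, ["PO3", "POz"], np.array([[0.0, -0.8, 0.6],
                                                         [0.1, -0.8, 0.6]]), events)
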
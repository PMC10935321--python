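"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from bioradar import radar_dsp, synth


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless, burst-free 3-min session with constant DC offset."""
    spec = synth.SessionSpec(
        baseline_duration=60.0, induction_duration=120.0,
        noise_sd=0.0, motion_burst_rate=0.0, rng_seed=2)
    radar, reference, truth, label = synth.generate_session(spec)
    return spec, radar, reference, truth, label


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise 8-min session (2-min baseline) for feature tests."""
    spec = synth.SessionSpec(
        baseline_duration=120.0, induction_duration=360.0, rng_seed=5)
    radar, reference, truth, label = synth.generate_session(spec)
    return spec, radar, reference, truth, label


@pytest.fixture(scope="session")
def clean_recovery(clean_session):
    """Demodulated displacement of the clean session."""
    _, radar, _, truth, _ = clean_session
    phase, displacement, track = radar_dsp.demodulate(radar)
    return displacement, track, truth


@pytest.fixture(scope="session")
def noisy_vitals(noisy_session):
    """Radar-branch vital signs of the noisy session."""
    from bioradar import vitals

    _, radar, _, truth, _ = noisy_session
    _, displacement, _ = radar_dsp.demodulate(radar)
    return vitals.vitals_from_phase(displacement, radar.fs), truth
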
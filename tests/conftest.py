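import dataclasses

import pytest

import eesmap as em


@pytest.fixture(scope="session")
def compact_setup():
    """Scaled-down study conditions: 6-rung ladder, 3 pulses per rung."""
    return em.study_defaults(current_stop_ua=60.0, pulses_per_current=3)


@pytest.fixture(scope="session")
def noisefree_session(compact_setup):
    """Deterministic noise-free session (no jitter) at 4 kHz."""
    protocol, sites, channels = compact_setup
    channels = [
        dataclasses.replace(c, noise_sd=0.0, latency_jitter_sd_ms=0.0)
        for c in channels
    ]
    session, truth = em.generate_session(
        protocol, sites, channels, seed=1, sampling_rate=4000.0
    )
    return session, truth, channels


@pytest.fixture(scope="session")
def noisy_session(compact_setup):
    """Moderately noisy session at 2 kHz with the preset noise levels."""
    protocol, sites, channels = compact_setup
    session, truth = em.generate_session(
        protocol, sites, channels, seed=11, sampling_rate=2000.0
    )
    return session, truth, channels
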
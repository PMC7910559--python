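import numpy as np
import pytest

from hvkit import (
    ChannelModel,
    GatingScheme,
    NoiseRundown,
    Solutions,
    simulate_recording,
    standard_step_protocol,
)
from hvkit.presets import load_preset


@pytest.fixture(scope="session")
def slhv1():
    return load_preset("SlHv1")


@pytest.fixture(scope="session")
def aohv1():
    return load_preset("AoHv1")


@pytest.fixture(scope="session")
def slhv1_seq():
    """Sequential three-state SlHv1-like scheme (total charge 5 e0)."""
    return load_preset("SlHv1-seq")


@pytest.fixture(scope="session")
def three_state_model():
    """Small hand-built three-state model with unequal step charges."""
    return ChannelModel(
        g_max=50.0,
        v_half_ref=10.0,
        s=8.0,
        scheme=GatingScheme(z_step=(1.5, 2.0), rate0=(0.05, 0.02)),
    )


@pytest.fixture(scope="session")
def slhv1_recording(slhv1):
    """Noisy 13-sweep step-family recording of the SlHv1 preset."""
    protocol = standard_step_protocol()
    return simulate_recording(
        slhv1, protocol, Solutions(), NoiseRundown(seed=11)
    )


@pytest.fixture(scope="session")
def clean_recording(slhv1):
    """Noise-free, rundown-free, leak-free SlHv1 recording."""
    protocol = standard_step_protocol()
    nr = NoiseRundown(sigma_I=0.0, rundown_per_sweep=1.0, g_leak=0.0, seed=0)
    return simulate_recording(slhv1, protocol, Solutions(), nr)
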
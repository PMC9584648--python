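from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegmarkers as em

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def montage10():
    return em.make_montage(10)


def make_recording(data: np.ndarray, fs: float = 250.0,
                   state: str = "synthetic") -> em.Recording:
    labels = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    return em.Recording(labels, fs, data, state)


@pytest.fixture
def noise_recording(rng):
    """Four channels of independent white noise, 30 s at 250 Hz."""
    return make_recording(rng.standard_normal((4, 250 * 30)))


@pytest.fixture(scope="session")
def lagged_pair_epochs():
    """Alpha-filtered epochs of a clean 90-degree-lag pair at 40 dB SNR."""
    graph = em.LagGraph(2, {(0, 1): (np.pi / 2, 1.0)})
    rec = em.gen_lagged_oscillators(graph, 250.0, 30.0, 40.0, seed=7)
    return em.bandpass_alpha(em.epoch(rec, 10.0))
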
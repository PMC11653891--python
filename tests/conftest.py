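import numpy as np
import pytest

import caimetrics as cm


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def clean_transient():
    """One noise-free transient with onset at frame 100 (15 fps, 450 frames)."""
    cfg = cm.SimConfig(n_neurons=1, duration_s=30, fps=15, rate_per_min=0,
                       noise_sd=0.0, amplitude_sigma=0.0, seed=0)
    truth = cm.GroundTruth(
        [np.array([100])],
        cm.NeuronMap(["n0"], np.array([[10.0, 10.0]])),
        np.array([2.0]), {},
    )
    traces = cm.render_traces(truth, cfg)
    return traces.values[:, 0], cfg


@pytest.fixture(scope="session")
def small_recording():
    """A modest synthetic recording shared by read-only tests."""
    cfg = cm.SimConfig(n_neurons=25, duration_s=200, rate_per_min=1.5,
                       noise_sd=0.05, seed=42)
    traces, truth = cm.simulate_recording(cfg)
    return traces, truth, cfg


def random_raster(rng, n_frames=None, n_neurons=None, p=None):
    """Random binary raster helper used by oracle-equivalence tests."""
    n_frames = n_frames or int(rng.integers(20, 201))
    n_neurons = n_neurons or int(rng.integers(2, 11))
    p = p if p is not None else rng.uniform(0.02, 0.4)
    states = (rng.random((n_frames, n_neurons)) < p).astype(np.uint8)
    return cm.BinaryRaster(states, method="spike", fps=15.0)
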
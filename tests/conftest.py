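import numpy as np
import pytest

import pulsepinn as pp
from pulsepinn.pinn_core import ModelConfig, init_params


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across the suite."""
    rec, ds, truth = pp.simulate(pp.SimConfig())
    return rec, ds, truth


@pytest.fixture(scope="session")
def std_dataset(default_sim):
    _, ds, _ = default_sim
    return pp.standardize(ds)


@pytest.fixture
def tiny_cfg():
    return ModelConfig(input_len=20, conv1_filters=4, conv2_filters=5, fc1_units=7)


@pytest.fixture
def tiny_params(tiny_cfg):
    return init_params(tiny_cfg, seed=1)


def make_tiny_dataset(
    n_beats=9, n_samples=20, seed=0, sessions=("a", "a", "a", "a", "a", "b", "b", "b", "b")
):
    rng = np.random.default_rng(seed)
    return pp.BeatDataset(
        waveforms=rng.normal(size=(n_beats, n_samples)),
        features=rng.normal(size=(n_beats, 3)),
        durations=np.ones(n_beats),
        t_start=np.arange(n_beats, dtype=float),
        session_ids=np.array(sessions[:n_beats]),
        sample_rate=30.0,
        labels=rng.normal(size=n_beats),
        standardized=True,
    )


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()


def two_gaussian_beat(
    duration=0.8,
    fs=100.0,
    amp=1.0,
    mu1=0.15,
    sigma1=0.04,
    delay=0.25,
    ratio=0.45,
    sigma2=0.06,
    y_true=None,
):
    """A clean synthetic beat with crests planted at mu1 and mu1+delay."""
    tau = np.arange(int(round(duration * fs))) / fs
    neg_dz = amp * (
        np.exp(-0.5 * ((tau - mu1) / sigma1) ** 2)
        + ratio * np.exp(-0.5 * ((tau - mu1 - delay) / sigma2) ** 2)
    )
    return pp.BeatRecord(
        x=-neg_dz,
        sample_rate=fs,
        duration=duration,
        t_start=0.0,
        beat_index=0,
        y_true=y_true,
    )
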
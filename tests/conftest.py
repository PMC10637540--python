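import numpy as np
import pytest

from dvpclust import ddtw, preprocess, synth_data


@pytest.fixture(scope="session")
def templates():
    """The four noise-free normalized class-template pulses, (4, 100)."""
    return synth_data.template_pulses()


@pytest.fixture(scope="session")
def planted_dataset():
    """400 pulses, approximately balanced classes, default noise, seed 1."""
    cfg = synth_data.balanced_config(n_pulses=400, seed=1)
    pulses, clinical, labels = synth_data.generate_dataset(cfg)
    X = preprocess.normalize_pulses(pulses)
    return X, clinical, labels


@pytest.fixture(scope="session")
def planted_ddtw(planted_dataset):
    """Pairwise DDTW matrix of the planted 400-pulse dataset (computed once)."""
    X, _, _ = planted_dataset
    return ddtw.pairwise_ddtw(X)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_pulses():
    """Factory for random smooth pulses (not class-shaped), for invariance tests."""
    return smooth_random_pulses


def smooth_random_pulses(n, rng, length=100):
    """Random smooth positive pulses for invariance tests (not class-shaped)."""
    t = np.linspace(0, 1, length)
    out = np.empty((n, length))
    for i in range(n):
        amp = rng.uniform(0.5, 1.5)
        c1, c2 = rng.uniform(0.15, 0.35), rng.uniform(0.5, 0.8)
        w1, w2 = rng.uniform(0.05, 0.12), rng.uniform(0.06, 0.15)
        a2 = rng.uniform(0.0, 0.6)
        out[i] = amp * np.exp(-0.5 * ((t - c1) / w1) ** 2) + a2 * np.exp(
            -0.5 * ((t - c2) / w2) ** 2
        )
    return out
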
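import numpy as np
import pytest

from brainlayers.synthetic import Coupling, GroupCoupling, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(seed=0, couplings=(), **kw):
    """A scaled-down synthetic study for fast unit tests (8 electrodes,
    24 trials/class, 2 recordings, 2-s paradigm trials with the source
    active over the whole trial)."""
    defaults = dict(
        n_electrodes=8,
        trials_per_class=24,
        n_recordings=2,
        trial_spacing=2.0,
        imagery_window=(0.0, 2.0),
        couplings=tuple(couplings),
        seed=seed,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.fixture
def small_cfg():
    return small_config()


def random_graph(rng, n=22, p=0.3):
    """Random symmetric binary adjacency without self-loops."""
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


def random_layer(rng, n=22):
    """Random weighted adjacency with unit diagonal, entries in [0, 1]."""
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return m
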
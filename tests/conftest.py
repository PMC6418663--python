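import numpy as np
import pytest

from nanopost import ForceFieldParams, PostArrayGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20170731)


@pytest.fixture
def array12():
    """Reference array: S_p = 12, d_p = 4.9 (mid-series geometry)."""
    return PostArrayGeometry(S_p=12.0, d_p=4.9)


@pytest.fixture
def ff_flexible():
    return ForceFieldParams(b=0.0)


@pytest.fixture
def ff_semiflexible():
    return ForceFieldParams(b=20.0)


def random_compact_chain(rng, N, spread=1.8):
    """Random but valid chain: bonds ~0.97, mild kinks, no overstretch."""
    from nanopost.chain import ChainState

    pos = np.zeros((N, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, N):
        kick = rng.normal(0, 0.35, 3)
        direction = direction + kick
        direction /= np.linalg.norm(direction)
        pos[i] = pos[i - 1] + 0.97 * direction
    pos += rng.normal(0, 0.01, pos.shape) * spread / 1.8
    return ChainState("linear", pos)
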
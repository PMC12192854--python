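import numpy as np
import pytest

from allonet.io import DomainMap, Ensemble
from allonet import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_domain_map():
    """40 residues over the five regions."""
    return DomainMap.from_ranges({
        "SH3": [[1, 10]], "SH2": [[11, 20]], "L": [[21, 22]],
        "SH1N": [[23, 30]], "SH1C": [[31, 40]],
    })


@pytest.fixture
def compact_dm():
    return synth.compact_domain_map()


@pytest.fixture
def small_ensemble(rng):
    """20 frames, 6 residues, isotropic jitter around a bent chain."""
    base = np.array([
        [0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.0, 2.0, 0.0],
        [9.0, 5.0, 1.0], [9.5, 8.5, 3.0], [8.0, 11.0, 6.0],
    ])
    coords = base[None] + 0.3 * rng.standard_normal((20, 6, 3))
    return Ensemble(coords, np.arange(1, 7))


def static_ensemble(n_frames=5):
    base = np.array([
        [0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.0, 2.0, 0.0],
        [9.0, 5.0, 1.0],
    ])
    return Ensemble(np.repeat(base[None], n_frames, axis=0), np.arange(1, 5))
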
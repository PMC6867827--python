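import numpy as np
import pytest

from transcoloc import make_cell_geometry


@pytest.fixture(scope="session")
def geometry():
    """Default 512x512 cell used across tests (8-um nucleus)."""
    return make_cell_geometry(1, (512, 512), 8.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Compact 256x256 cell for cheaper simulations."""
    return make_cell_geometry(3, (256, 256), 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mixture_intensities(seed, n=2611, cv=0.15, single=1000.0, probs=None):
    """Pooled spot intensities from a copy-number mixture (shared helper)."""
    rng = np.random.default_rng(seed)
    probs = probs or {1: 0.25, 2: 0.20, 3: 0.15, 4: 0.12, 5: 0.08, 6: 0.20}
    ks = rng.choice(list(probs), p=list(probs.values()), size=n)
    s2 = np.log1p(cv**2)
    return ks * single * rng.lognormal(-s2 / 2.0, np.sqrt(s2), n), ks
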
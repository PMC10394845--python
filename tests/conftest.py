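import numpy as np
import pytest

from tasselseg.io_formats import PointCloud
from tasselseg.synthetic import TasselSpec, generate_tassel


@pytest.fixture(scope="session")
def small_tassel():
    """One mid-size labeled tassel plus ground truth (deterministic)."""
    return generate_tassel(TasselSpec(seed=11))


@pytest.fixture(scope="session")
def tiny_tassel():
    """A light tassel for fast tests."""
    spec = TasselSpec(n_branches=(6, 8), stem_length=(25.0, 30.0),
                      branch_length=(10.0, 18.0), seed=7)
    return generate_tassel(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng, n, colors=False, labels=False, scale=1.0):
    coords = rng.uniform(-scale, scale, (n, 3))
    return PointCloud(
        coords,
        colors=rng.uniform(0, 1, (n, 3)) if colors else None,
        labels=rng.integers(0, 2, n) if labels else None,
    )
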
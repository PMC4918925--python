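import numpy as np
import pytest

from glyconnect.synthetic import PhantomRegion, TensorPhantomConfig


def random_weighted_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric non-negative weight matrix with approximately the given density."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    return w + w.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_graphs():
    """Deterministic batch of small random weighted graphs (some disconnected)."""
    r = np.random.default_rng(7)
    return [
        random_weighted_graph(n, dens, r)
        for n in (5, 8, 10, 12)
        for dens in (0.25, 0.5, 0.9)
    ]


@pytest.fixture
def xbar_phantom():
    """Two terminal regions joined by an x-oriented anisotropic bar."""
    bar = PhantomRegion(
        bbox=((0, 20), (3, 7), (3, 7)),
        direction=(1.0, 0.0, 0.0),
        eigvals=(1.7e-3, 0.2e-3, 0.2e-3),
    )
    left = PhantomRegion(
        bbox=((0, 3), (3, 7), (3, 7)),
        direction=(1.0, 0.0, 0.0),
        eigvals=(1.7e-3, 0.2e-3, 0.2e-3),
        label=1,
    )
    right = PhantomRegion(
        bbox=((17, 20), (3, 7), (3, 7)),
        direction=(1.0, 0.0, 0.0),
        eigvals=(1.7e-3, 0.2e-3, 0.2e-3),
        label=2,
    )
    return TensorPhantomConfig(
        grid_shape=(20, 10, 10),
        voxel_size=(2.0, 2.0, 2.0),
        field_spec=[bar, left, right],
        background_eigvals=(0.7e-3, 0.7e-3, 0.7e-3),
        noise_sd=0.0,
        seed=3,
    )
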
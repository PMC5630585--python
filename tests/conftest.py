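import numpy as np
import pytest

from uscut.image_io import PointPx, UltrasoundImage
from uscut.radial_graph import GraphParams, RadialGraph


def disc_image(size=128, center=(64.0, 64.0), radius=30.0, inside=20, outside=120):
    """Noiseless hypoechoic disc on a bright background."""
    ys, xs = np.mgrid[0:size, 0:size]
    px = np.where(np.hypot(xs - center[0], ys - center[1]) <= radius, inside, outside)
    return UltrasoundImage(px.astype(np.uint8), source_id="disc")


def analytic_disc_mask(size=128, center=(64.0, 64.0), radius=30.0):
    ys, xs = np.mgrid[0:size, 0:size]
    from uscut.image_io import BinaryMask

    return BinaryMask((np.hypot(xs - center[0], ys - center[1]) <= radius).astype(np.uint8))


def random_graph(rng, n_rays=None, n_nodes=None, delta_r=None, int_caps=True):
    """Small radial graph with random terminal weights (no image behind it)."""
    K = n_rays or int(rng.integers(3, 9))
    N = n_nodes or int(rng.integers(3, 13))
    dr = delta_r if delta_r is not None else int(rng.integers(0, 4))
    params = GraphParams(K, N, max(N, 10), dr, 1)
    g = RadialGraph(
        params=params,
        seed=PointPx(0.0, 0.0),
        positions=np.zeros((K, N, 2)),
        grays=np.zeros((K, N)),
    )
    g.term_sink = rng.random((K, N)) < 0.5
    g.term_sink[:, 0] = False
    g.term_sink[:, -1] = True
    caps = rng.integers(0, 51, (K, N)) if int_caps else rng.uniform(0, 50, (K, N))
    g.term_cap = np.asarray(caps, dtype=float)
    return g


@pytest.fixture
def disc():
    return disc_image()


@pytest.fixture
def disc_truth():
    return analytic_disc_mask()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
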
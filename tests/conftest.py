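import numpy as np
import pytest

from macde import synthetic


@pytest.fixture(scope="session")
def star_phantom():
    """Default star image + exact ground-truth mask (160x160, deterministic)."""
    return synthetic.make_star()


@pytest.fixture(scope="session")
def noisy_circle_phantom():
    return synthetic.make_noisy_circle(seed=0)


@pytest.fixture(scope="session")
def blob_phantom():
    return synthetic.make_concave_blob()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_edm(edges: np.ndarray) -> np.ndarray:
    """O(N*E) nearest-edge scan: the independent distance-map oracle."""
    rr, cc = np.nonzero(edges)
    h, w = edges.shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - rr) ** 2 + (xx[..., None] - cc) ** 2
    return np.sqrt(d2.min(axis=-1))


def brute_force_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """O(|A|*|B|) double-loop directed Hausdorff oracle.

    Works in squared distances with one final sqrt — the conventional
    formulation, so values are bitwise comparable with sqrt(max min d^2).
    """
    best = 0.0
    for p in a:
        nearest = min(
            float((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2) for q in b
        )
        best = max(best, nearest)
    return float(np.sqrt(best))
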
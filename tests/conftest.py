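import numpy as np
import pytest

from drtdc import rheology as rh
from drtdc import synthetic as syn


def random_convex_polygon(rng: np.random.Generator, n: int = 40,
                          radius: float = 10.0) -> np.ndarray:
    """Random convex polygon: convex hull of points on a noisy circle."""
    from scipy.spatial import ConvexHull

    phi = np.sort(rng.uniform(-np.pi, np.pi, n))
    r = radius * (1.0 + rng.uniform(-0.25, 0.25, n))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    hull = ConvexHull(pts)
    return pts[hull.vertices]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cfg():
    """Channel configuration consistent with the simulator's synthetic world."""
    return rh.ChannelConfig(
        calibration_table=rh.linear_elastic_table(142.0, gain=syn.STRAIN_GAIN))


@pytest.fixture(scope="session")
def default_sim():
    """One noiseless simulated transit with HL60-like defaults (cached)."""
    spec = syn.SyntheticCellSpec()
    gt, contours = syn.simulate_trace(spec)
    return spec, gt, contours
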
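import numpy as np
import pytest

from dbsuggest.lead_model import build_lead
from dbsuggest.spheres import Sphere
from dbsuggest.volumes import make_reference_grid


@pytest.fixture
def straight_lead():
    """Ideal vertical lead: tip at the origin, levels at z = 0.75 + 2k."""
    return build_lead((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), roll_angle=0.0)


@pytest.fixture
def sweetspot_sphere():
    """Analytic sweet-spot ball of radius 2.5 mm near the lead's mid levels."""
    return Sphere(center=(1.5, 0.0, 3.75), radius=2.5)


@pytest.fixture
def fine_grid():
    """0.25 mm reference grid around the origin."""
    return make_reference_grid((0.0, 0.0, 0.0), half_extent=6.0, resolution=0.25)


def montecarlo_sphere_overlap(r1, d, r2, n=200_000, rng=None):
    """Independent MC oracle: overlap volume of spheres (r1 at origin,
    r2 at distance d) by uniform sampling inside the smaller sphere."""
    rng = rng or np.random.default_rng(0)
    r_small, r_big = min(r1, r2), max(r1, r2)
    if r_small == 0:
        return 0.0
    # uniform points in the smaller sphere, centered at origin
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = v * (r_small * rng.uniform(size=(n, 1)) ** (1.0 / 3.0))
    # place the big sphere at (d, 0, 0) relative to the small one
    frac = np.mean(np.sum((pts - [d, 0.0, 0.0]) ** 2, axis=1) <= r_big**2)
    return frac * 4.0 / 3.0 * np.pi * r_small**3
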
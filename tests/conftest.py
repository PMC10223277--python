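import numpy as np
import pytest

from fazmorph import ContourMeta, PixelScale, PointSet


@pytest.fixture
def meta():
    return ContourMeta(
        eye_id="eye01", plexus="SCP", cohort="DM1", observer="C", series=1,
        criterion="INITIAL", width_mm=3.0, image_cols=64, image_rows=64,
    )


@pytest.fixture
def unit_square(meta):
    return PointSet(np.array([[1, 1], [0, 0], [1, 0], [0, 1]]), meta)


@pytest.fixture
def identity_scale():
    return PixelScale.isotropic(1.0)


def random_star_contour(rng, n=200, r0=50.0):
    """Float point cloud on a random star-shaped harmonic boundary."""
    n_h = rng.integers(1, 4)
    ks = rng.choice(np.arange(2, 9), size=n_h, replace=False)
    amps = rng.uniform(0.01, 0.25 / n_h, n_h)
    phis = rng.uniform(0, 2 * np.pi, n_h)
    theta = rng.uniform(0, 2 * np.pi, n)
    r = r0 * (1 + sum(a * np.cos(k * theta + p) for k, a, p in zip(ks, amps, phis)))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
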
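import numpy as np
import pytest

from memfluct import GridField, RandomStream, SyntheticSpec


@pytest.fixture
def rng():
    return RandomStream(12345)


@pytest.fixture
def small_spec():
    """A quick 32x32 ensemble spec used across modules."""
    return SyntheticSpec(
        Kc=25.0, Kd=2.4, Ke=26.7, box_lengths=(16.0, 16.0),
        grid_spacing=0.5, n_frames=200, seed=7,
    )


@pytest.fixture
def sinusoid_surfaces():
    """Single-mode height field + flat thickness on a 40x40 grid."""
    L, nx = 20.0, 40
    x = np.arange(nx) * (L / nx)
    h = 1.0 * np.sin(2 * np.pi * x / L)[:, None] * np.ones((1, nx))
    height = GridField(h - h.mean(), (L, L), kind="height")
    thickness = GridField(np.full((nx, nx), 4.0), (L, L), kind="thickness")
    return height, thickness


def theory_height_variance(spec: SyntheticSpec) -> float:
    """Oracle: direct sum of Helfrich mode variances over the q-grid."""
    nx, ny = spec.grid_shape
    lx, ly = spec.box_lengths
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=lx / nx)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=ly / ny)
    q2 = qx[:, None] ** 2 + qy[None, :] ** 2
    with np.errstate(divide="ignore"):
        var = 1.0 / (spec.area * spec.Kc * q2**2)
    var[0, 0] = 0.0
    return float(var.sum())
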
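import numpy as np
import pytest

from tubulometry import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A modest noisy two-channel phantom shared across test modules."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        n_tubules=25,
        diameter_mixture=[(0.5, 25.0, 2.0), (0.5, 45.0, 4.0)],
        tilt_jitter_deg=15.0,
        noise_sd=40.0,
        coloc_fraction=0.6,
        seed=42,
        length_um=250.0,
    )
    vol_a, vol_b, truth = generate_phantom(spec)
    return spec, vol_a, vol_b, truth


def brute_force_disc(radius_vox: float, center=(0.0, 0.0), half_extent: int = 64):
    """Independent 2-D disc rasterizer: pixel centers within radius of center."""
    yy, xx = np.mgrid[-half_extent : half_extent + 1, -half_extent : half_extent + 1]
    m = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_vox**2
    return np.column_stack([yy[m], xx[m]]).astype(float)
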
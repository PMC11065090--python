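import numpy as np
import pytest

import shgmorph as sm
from shgmorph.phantom import MeshPhantomParams, _pore_density_for_targets, generate_mesh_phantom

PS = sm.DEFAULT_PIXEL_SIZE_UM


def make_line_image(theta_deg=30.0, size=256, width_um=2.23, peak=150.0):
    """Analytic straight Gaussian ridge through the image center."""
    import math

    s_px = (width_um / PS) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    th = math.radians(theta_deg)
    d = np.abs(-(yy - size / 2) * math.cos(th) + (xx - size / 2) * math.sin(th))
    img = peak * np.exp(-0.5 * (d / s_px) ** 2) * (d <= 4 * s_px)
    return img


def make_line_scan(theta_deg=30.0, size=256, width_um=2.23, peak=150.0):
    img = make_line_image(theta_deg, size, width_um, peak)
    return sm.MultichannelScan(img, img, np.full_like(img, 1.0), PS, 1.0)


def mesh_sample(target_pore_um2=40.0, size=256, noise="poisson", seed=0, width_um=2.1):
    side = size * PS
    params = MeshPhantomParams(
        image_size=size,
        pore_density_per_mm2=_pore_density_for_targets(target_pore_um2, side**2, 4 * side),
        fiber_width_mean_um=width_um,
        noise_model=noise,
        seed=seed,
    )
    return generate_mesh_phantom(params)


@pytest.fixture(scope="session")
def mesh_sample_poisson():
    """One realistic mesh scene reused by read-only tests."""
    return mesh_sample()


@pytest.fixture(scope="session")
def mesh_summary(mesh_sample_poisson):
    s = mesh_sample_poisson
    return sm.summarize_sample(s.scan, s.roi), s
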
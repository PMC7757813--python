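import numpy as np
import pytest

import myoseg as ms


@pytest.fixture(scope="session")
def hex_phantom_small():
    """Modest hexagonal phantom with gradient + noise, shared across tests."""
    spec = ms.PhantomSpec(width_px=600, height_px=600, resolution=0.462,
                          layout="hexagonal", hex_pitch_um=51.0,
                          boundary_width_um=6.0, contrast_ratio=2.5,
                          illumination=0.3, noise_sd=0.05, rng_seed=11)
    img, truth = ms.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def hex_pipeline_run(hex_phantom_small):
    """Full pipeline output on the shared phantom."""
    spec, img, truth = hex_phantom_small
    labels, table, summary = ms.run_pipeline(img)
    return spec, img, truth, labels, table, summary


def make_bar_image(shape, width_px, angle_deg, value=200.0, background=20.0,
                   supersample=4):
    """Anti-aliased bright bar of given width through the image centre.

    Returns (image, signed_distance) where signed_distance[y, x] is the
    perpendicular distance of pixel (x, y) from the bar's true centerline.
    """
    h, w = shape
    theta = np.deg2rad(angle_deg)
    n = np.array([-np.sin(theta), np.cos(theta)])  # unit normal (x, y)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ss = supersample
    yy, xx = np.mgrid[0:h * ss, 0:w * ss]
    xs = xx / ss - (ss - 1) / (2 * ss)
    ys = yy / ss - (ss - 1) / (2 * ss)
    d = (xs - cx) * n[0] + (ys - cy) * n[1]
    fine = np.where(np.abs(d) <= width_px / 2.0, value, background)
    img = fine.reshape(h, ss, w, ss).mean(axis=(1, 3))
    yy, xx = np.mgrid[0:h, 0:w]
    dist = (xx - cx) * n[0] + (yy - cy) * n[1]
    return img, dist
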
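"""Shared fixtures: small rendered cells and cytometry tables, built once per
session so the suite stays fast."""

import numpy as np
import pytest

from mitocohort.synthgen import (
    CytometrySimConfig,
    ImageSimConfig,
    generate_network,
    render_cell_image,
    simulate_events,
)

IMG_SHAPE = (180, 180)
CELL_R = 66.0


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, blur-free optics: thresholding recovers the raster exactly."""
    return ImageSimConfig(
        image_size_px=IMG_SHAPE, cell_radius_px=70.0, psf_sigma_px=0.0,
        noise_gaussian_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def noisy_cfg():
    return ImageSimConfig(
        image_size_px=IMG_SHAPE, cell_radius_px=70.0, psf_sigma_px=1.0,
        noise_gaussian_sd=3.0, seed=1,
    )


@pytest.fixture(scope="session")
def small_network():
    return generate_network(CELL_R, 15.0, 4, 0.01, tube_radius_px=1, seed=4)


@pytest.fixture(scope="session")
def clean_cell(small_network, clean_cfg):
    return render_cell_image(small_network, clean_cfg, cell_id="clean")


@pytest.fixture(scope="session")
def control_tubes():
    """One control subject's three tubes at moderate event counts."""
    cfg = CytometrySimConfig(seed=11, n_lymph=8000, n_mono=3000)
    return cfg, {c: simulate_events(cfg, c, "S000") for c in ("basal", "PMA", "CCCP")}
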
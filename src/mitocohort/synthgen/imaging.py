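"""Confocal-like rendering of network ground truths into single-slice images.

The optical model is deliberately simple: constant fluorophore density inside
the rasterized tubes, a dim cytoplasmic background inside the cell, a Gaussian
point-spread function, additive Gaussian read noise and optional Poisson shot
noise.  The paired nuclear channel is a filled blurred disk, mimicking a DAPI
counterstain used only to locate cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .networks import NetworkGroundTruth, cell_mask, rasterize_network

# intensity levels before blur/noise (8-bit-like scale)
BACKGROUND_LEVEL = 10.0
CYTOPLASM_LEVEL = 60.0
TUBE_LEVEL = 220.0
NUCLEUS_LEVEL = 180.0


@dataclass(frozen=True)
class ImageSimConfig:
    """Geometry, optics and noise of one synthetic acquisition."""

    image_size_px: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.05
    cell_radius_px: float = 70.0
    psf_sigma_px: float = 1.0
    noise_gaussian_sd: float = 3.0
    noise_poisson_scale: float = 0.0  # photons per intensity unit; 0 disables
    nucleus_radius_px: float = 25.0
    nucleus_offset: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be >= 0")
        h, w = self.image_size_px
        if 2 * self.cell_radius_px + 2 > min(h, w):
            raise ValueError("cell does not fit inside the image")


@dataclass
class CellImage:
    """One cell's confocal slice plus calibration, the unit of morphometry."""

    mito_channel: np.ndarray
    nucleus_channel: np.ndarray | None
    pixel_size_um: float
    cell_id: str
    cell_type: str = "monocyte"  # or "lymphocyte"
    truth: NetworkGroundTruth | None = None


def render_cell_image(
    truth: NetworkGroundTruth, cfg: ImageSimConfig, cell_id: str = "cell",
    cell_type: str = "monocyte",
) -> CellImage:
    """Rasterize a network ground truth into a noisy single-slice image.

    The returned :class:`CellImage` carries ``truth`` unchanged.  With
    ``psf_sigma_px = 0`` and zero noise the tube mask is recoverable exactly by
    thresholding, which anchors the morphometry tests.
    """
    if truth.cell_radius_px > cfg.cell_radius_px:
        raise ValueError("ground truth was generated for a larger cell than cfg allows")
    shape = tuple(cfg.image_size_px)
    # integer centre so the raster pixelation matches the generator's local grid
    center = (shape[0] // 2, shape[1] // 2)
    rng = np.random.default_rng(cfg.seed)

    # the drawn cell is the truth's own disk, keeping the area ratio exact
    cmask = cell_mask(shape, center, truth.cell_radius_px)
    tubes = rasterize_network(truth, shape, center)
    img = np.full(shape, BACKGROUND_LEVEL, dtype=float)
    img[cmask] = CYTOPLASM_LEVEL
    img[tubes] = TUBE_LEVEL

    nuc = np.full(shape, BACKGROUND_LEVEL, dtype=float)
    ncenter = (center[0] + cfg.nucleus_offset[0], center[1] + cfg.nucleus_offset[1])
    nuc[cell_mask(shape, ncenter, cfg.nucleus_radius_px)] = NUCLEUS_LEVEL

    if cfg.psf_sigma_px > 0:
        img = gaussian_filter(img, cfg.psf_sigma_px)
        nuc = gaussian_filter(nuc, cfg.psf_sigma_px)
    if cfg.noise_poisson_scale > 0:
        img = rng.poisson(img * cfg.noise_poisson_scale) / cfg.noise_poisson_scale
        nuc = rng.poisson(nuc * cfg.noise_poisson_scale) / cfg.noise_poisson_scale
    if cfg.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_gaussian_sd, shape)
        nuc = nuc + rng.normal(0.0, cfg.noise_gaussian_sd, shape)
    return CellImage(
        mito_channel=np.clip(img, 0.0, None),
        nucleus_channel=np.clip(nuc, 0.0, None),
        pixel_size_um=cfg.pixel_size_um,
        cell_id=cell_id,
        cell_type=cell_type,
        truth=truth,
    )
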
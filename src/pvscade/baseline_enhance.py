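"""Algorithmic enhancement baselines: white top-hat, CLAHE, and Laplacian
sharpening.

Each baseline maps a [0,1] part image to a [0,1] image (min-max renormalized
so CNR comparisons against the learned enhancer share a common range). These
methods brighten all small/high-frequency structure, not just ePVS, which is
exactly the behavior the learned enhancer is meant to improve on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure, morphology

from .preprocess import minmax


@dataclass(frozen=True)
class BaselineConfig:
    tophat_radius: int = 3
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    laplacian_weight: float = 1.0

    def __post_init__(self):
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.laplacian_weight <= 0:
            raise ValueError("laplacian_weight must be positive")


def _check_unit_image(image) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    return image


def tophat_enhance(image, radius: int = 3) -> np.ndarray:
    """White top-hat residual (image minus its disk opening) added back to
    the image, then renormalized: brightens structures smaller than the disk."""
    image = _check_unit_image(image)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(image.shape):
        raise ValueError(f"structuring element radius {radius} too large for image {image.shape}")
    residual = morphology.white_tophat(image, morphology.disk(radius))
    return minmax(image + residual)


def clahe_enhance(image, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, renormalized to [0,1]."""
    image = _check_unit_image(image)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    tr, tc = tile_grid
    if tr > image.shape[0] or tc > image.shape[1]:
        raise ValueError(f"tile grid {tile_grid} does not fit image {image.shape}")
    kernel = (max(1, image.shape[0] // tr), max(1, image.shape[1] // tc))
    out = exposure.equalize_adapthist(np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit)
    return minmax(out)


LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]], dtype=np.float32)


def laplacian_enhance(image, weight: float = 1.0) -> np.ndarray:
    """Unsharp-style edge boost: image - weight * (4-neighbor Laplacian),
    renormalized to [0,1]."""
    image = _check_unit_image(image)
    if weight <= 0:
        raise ValueError("weight must be positive")
    lap = ndi.convolve(image, LAPLACIAN_KERNEL, mode="reflect")
    return minmax(image - weight * lap)
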
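"""Preprocessing: ROI extraction, bilinear standardization to 80x96,
per-image [0,1] normalization, enhancement-target construction, and count
normalization.

The enhancement target for a part is built by adding the binary ePVS mask to
the normalized image and min-max renormalizing to [0,1]; masked pixels end up
at the top of the intensity range while preserving the background's relative
contrast, which is what the image-regression enhancer learns to reproduce.
Counts are mapped to [0,1] by dividing by the maximum count (48 by default)
and back by multiplying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

UNIT_SHAPE = (80, 96)  # rows x cols working size
COUNT_MAX_DEFAULT = 48


def minmax(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0,1]; a constant array maps to all zeros (tie-break)."""
    values = np.asarray(values, dtype=np.float32)
    if values.size == 0:
        raise ValueError("empty image")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values, dtype=np.float32)
    return ((values - lo) / (hi - lo)).astype(np.float32)


def normalize_intensity(raw) -> np.ndarray:
    """Per-image min-max normalization of a nonnegative 16-bit grid to [0,1]."""
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("empty image")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be nonnegative")
    return minmax(raw.astype(np.float32))


def resize_image(image, out_shape=UNIT_SHAPE) -> np.ndarray:
    """Plain bilinear resampling (no anti-alias prefilter)."""
    out = _sk_resize(
        np.asarray(image, dtype=np.float32),
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(np.float32)


def resize_mask(mask, out_shape=UNIT_SHAPE) -> np.ndarray:
    """Nearest-neighbor resampling re-binarized at 0.5 so labels stay binary."""
    out = _sk_resize(
        np.asarray(mask, dtype=np.float32),
        out_shape,
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return (out > 0.5).astype(np.uint8)


def crop_and_resize(slice_grid, roi_mask, hemisphere: str, out_shape=UNIT_SHAPE) -> np.ndarray:
    """Extract one hemisphere's ROI from a whole slice and standardize its size.

    The ROI mask's bounding region is split at its column midpoint into a
    left and a right half (image-coordinate convention: "left" = lower
    column indices). Pixels outside the ROI are zeroed, the hemisphere
    component is cropped to its bounding box, and the crop is bilinearly
    resampled to `out_shape`.
    """
    slice_grid = np.asarray(slice_grid, dtype=np.float32)
    roi = np.asarray(roi_mask) > 0
    if slice_grid.shape != roi.shape:
        raise ValueError(f"slice shape {slice_grid.shape} != roi shape {roi.shape}")
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    if not roi.any():
        raise ValueError(f"ROI mask is empty (hemisphere={hemisphere})")
    import scipy.ndimage as ndi

    labels, n = ndi.label(roi, structure=np.ones((3, 3), bool))
    if n == 1:
        hemi = roi
    else:
        # split the ROI's bounding region at its column midpoint and keep the
        # components whose centroids fall on the requested side
        cols = np.where(roi.any(axis=0))[0]
        mid = (cols[0] + cols[-1] + 1) / 2
        centroids = ndi.center_of_mass(roi, labels, range(1, n + 1))
        if hemisphere == "left":
            keep = [i + 1 for i, (_, cx) in enumerate(centroids) if cx < mid]
        else:
            keep = [i + 1 for i, (_, cx) in enumerate(centroids) if cx >= mid]
        if not keep:
            raise ValueError(f"empty {hemisphere} hemisphere ROI")
        hemi = np.isin(labels, keep)
    rows = np.where(hemi.any(axis=1))[0]
    cols = np.where(hemi.any(axis=0))[0]
    masked = np.where(hemi, slice_grid, 0.0)
    crop = masked[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return resize_image(crop, out_shape)


def make_enhancement_target(image, mask) -> np.ndarray:
    """Target = minmax(image + mask): masked pixels pushed to the top of the
    range; an empty mask leaves the image unchanged."""
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0,1]")
    binary = (mask > 0).astype(np.float32)
    if not binary.any():
        return image.copy()
    return minmax(image + binary)


def normalize_count(count: int, count_max: int = COUNT_MAX_DEFAULT, clip: bool = False) -> float:
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count > count_max:
        if not clip:
            raise ValueError(f"count {count} exceeds count_max {count_max}")
        count = count_max
    return count / count_max


def denormalize_count(value: float, count_max: int = COUNT_MAX_DEFAULT) -> float:
    return float(np.clip(value, 0.0, 1.0)) * count_max


@dataclass(frozen=True)
class CountLabel:
    count: int
    normalized: float
    count_max: int = COUNT_MAX_DEFAULT


@dataclass(frozen=True)
class PreparedPart:
    """A standardized part: [0,1] input at the working size, its enhancement
    target, the resized binary mask, and the normalized count label."""

    input_image: np.ndarray
    target: np.ndarray
    mask: np.ndarray
    label: CountLabel


def prepare_part(part, out_shape=UNIT_SHAPE, count_max: int = COUNT_MAX_DEFAULT) -> PreparedPart:
    """Standardize one phantom/real part: resize raw (bilinear) and mask
    (nearest), normalize to [0,1], build the enhancement target.

    The stored count is kept as the label even if resizing merges puncta:
    labels reflect pre-resize ground truth.
    """
    resized = resize_image(part.raw, out_shape)
    mask = resize_mask(part.mask, out_shape)
    image = minmax(resized)
    target = make_enhancement_target(image, mask)
    label = CountLabel(count=part.count, normalized=normalize_count(part.count, count_max), count_max=count_max)
    return PreparedPart(input_image=image, target=target, mask=mask, label=label)
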
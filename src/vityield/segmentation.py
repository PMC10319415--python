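"""Plant/soil segmentation of RGB canopy images.

The split uses the excess-green index (2g - r - b on channel-normalized
values) thresholded by Otsu's method (or a fixed threshold), followed by a
3x3 morphological opening and closing and removal of small components.
The two output streams are complementary maskings of the input, so their
sum reconstructs the original image exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle, opening
from skimage.morphology import remove_small_objects

from .errors import InvalidArgumentError

__all__ = ["SegmentedPair", "excess_green", "segment_plant_soil", "mask_iou"]

_SE3 = footprint_rectangle((3, 3))


@dataclass
class SegmentedPair:
    plant_image: np.ndarray  # soil pixels zeroed
    soil_image: np.ndarray   # plant pixels zeroed
    plant_mask: np.ndarray   # bool

    @property
    def plant_fraction(self) -> float:
        return float(self.plant_mask.mean())


def excess_green(image: np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index on channel-normalized RGB.

    Channels are divided by their per-pixel sum before computing
    ``2g - r - b``; zero-sum (black) pixels map to 0. Output range is
    [-1, 2].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidArgumentError("excess_green expects an HxWx3 RGB image")
    total = image.sum(axis=2)
    safe = np.where(total > 0, total, 1.0)
    r, g, b = (image[:, :, c] / safe for c in range(3))
    exg = 2.0 * g - r - b
    exg[total == 0] = 0.0
    return exg


def segment_plant_soil(image: np.ndarray, threshold_mode: str = "otsu",
                       fixed_threshold: float = 0.1,
                       min_region: int = 16) -> SegmentedPair:
    """Split ``image`` into plant and soil streams.

    threshold_mode "otsu" picks the threshold from the ExG histogram; a
    constant image degenerates the histogram, in which case an all-soil mask
    is returned with a warning. "fixed" uses ``fixed_threshold``.
    """
    image = np.asarray(image)
    exg = excess_green(image)
    if threshold_mode == "otsu":
        if np.ptp(exg) < 1e-12:
            warnings.warn("constant excess-green field; returning all-soil mask")
            mask = np.zeros(exg.shape, dtype=bool)
        else:
            mask = exg > threshold_otsu(exg)
    elif threshold_mode == "fixed":
        mask = exg > fixed_threshold
    else:
        raise InvalidArgumentError(f"unknown threshold mode: {threshold_mode}")

    if mask.any():
        mask = closing(opening(mask, _SE3), _SE3)
        if min_region > 1:
            # drop components strictly smaller than min_region pixels
            mask = remove_small_objects(mask, max_size=min_region - 1)

    plant = np.where(mask[:, :, None], image, 0)
    soil = np.where(mask[:, :, None], 0, image)
    return SegmentedPair(plant.astype(image.dtype), soil.astype(image.dtype), mask)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 if both empty)."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
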
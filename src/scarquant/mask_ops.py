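"""Post-processing of classifier masks: cropping, dilation, artifact removal, rendering.

All operations preserve the mask/image shape; cropping zeroes pixels outside
the region of interest rather than resizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from scarquant.image_io import validate_rgb

_STRUCTURE8 = np.ones((3, 3), bool)  # 8-connectivity for components


@dataclass(frozen=True)
class ROI:
    """Half-open rectangle [top, bottom) x [left, right) in pixel indices."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom and 0 <= self.left < self.right):
            raise ValueError(f"empty or negative ROI {self}")

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.bottom > shape[0] or self.right > shape[1]:
            raise ValueError(f"ROI {self} exceeds mask shape {shape}")


def _validate_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {mask.shape}")
    return mask.astype(bool)


def crop_to_roi(mask: np.ndarray, roi: ROI) -> np.ndarray:
    """Zero all mask pixels outside the ROI; shape is unchanged."""
    mask = _validate_bool(mask)
    roi.check_within(mask.shape)
    out = np.zeros_like(mask)
    out[roi.top : roi.bottom, roi.left : roi.right] = mask[roi.top : roi.bottom, roi.left : roi.right]
    return out


def dilate_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with a disk structuring element.

    Radius 0 is the identity. The disk is skimage's Euclidean disk, so
    radius 1 is the 5-pixel plus shape (diagonals excluded).
    """
    mask = _validate_bool(mask)
    if radius < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=disk(radius))


def remove_artifacts(
    mask: np.ndarray,
    exclusion: list[ROI] | None = None,
    min_area: int = 0,
) -> np.ndarray:
    """Remove user-marked artifact regions (e.g. bubbles) and small components.

    Pixels inside every exclusion ROI are set false, then 8-connected
    components smaller than ``min_area`` pixels are dropped. Idempotent.
    """
    mask = _validate_bool(mask).copy()
    for roi in exclusion or []:
        roi.check_within(mask.shape)
        mask[roi.top : roi.bottom, roi.left : roi.right] = False
    if min_area > 0 and mask.any():
        labels, _ = ndimage.label(mask, structure=_STRUCTURE8)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = (sizes >= min_area)[labels]
    return mask


def render_masked(image: np.ndarray, mask: np.ndarray, color: tuple[int, int, int] = (255, 255, 255)) -> np.ndarray:
    """Paint masked pixels with a solid color (default white), others unchanged."""
    image = validate_rgb(image)
    mask = _validate_bool(mask)
    if mask.shape != image.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.shape[:2]}")
    out = image.copy()
    out[mask] = np.asarray(color, dtype=np.uint8)
    return out


def isolate(image: np.ndarray, mask: np.ndarray, background: tuple[int, int, int] = (255, 255, 255)) -> np.ndarray:
    """Keep masked pixels at their original colors on a blank background."""
    image = validate_rgb(image)
    mask = _validate_bool(mask)
    if mask.shape != image.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.shape[:2]}")
    out = np.empty_like(image)
    out[:] = np.asarray(background, dtype=np.uint8)
    out[mask] = image[mask]
    return out
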
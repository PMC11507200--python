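"""Reading, writing and splitting of scanned-slide raster images.

Slides typically carry several serial sections that are scanned as one image;
analysis operates on one section at a time, so a scan is split into
single-section sub-images by verbatim cropping (no resampling). All images are
8-bit RGB ``(H, W, 3)`` uint8 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

READ_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
WRITE_SUFFIXES = {".png", ".tif", ".tiff"}  # JPEG is lossy; refused for outputs


class ImageFormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


def _as_rgb8(arr: np.ndarray, source: str) -> np.ndarray:
    """Coerce a decoded raster to (H, W, 3) uint8.

    Grayscale planes are replicated to three channels; an alpha channel is
    dropped; 16-bit samples are rescaled with round(v * 255 / 65535).
    """
    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ImageFormatError(f"{source}: expected grayscale or RGB(A) raster, got shape {arr.shape}")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return np.ascontiguousarray(arr)
    if arr.dtype == np.uint16:
        return np.round(arr.astype(np.float64) * 255.0 / 65535.0).astype(np.uint8)
    raise ImageFormatError(f"{source}: unsupported sample type {arr.dtype}; expected 8- or 16-bit integer")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an (H, W, 3) uint8 RGB array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in READ_SUFFIXES:
        raise ImageFormatError(f"{path}: unsupported format {path.suffix!r}; expected one of {sorted(READ_SUFFIXES)}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failure -> explicit format error
        raise ImageFormatError(f"{path}: could not decode image ({exc})") from exc
    return _as_rgb8(np.asarray(arr), str(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an RGB uint8 array losslessly (PNG or TIFF only)."""
    path = Path(path)
    if path.suffix.lower() not in WRITE_SUFFIXES:
        raise ImageFormatError(f"{path}: refusing lossy/unsupported output format {path.suffix!r}; use PNG or TIFF")
    image = validate_rgb(image)
    iio.imwrite(path, image)


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Validate an (H, W, 3) uint8 RGB array, returning it unchanged."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 channel values, got {image.dtype}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    return image


@dataclass(frozen=True)
class SplitBoundary:
    """Half-open [top, bottom) extent of one sub-image along the split axis."""

    top: int
    bottom: int

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom):
            raise ValueError(f"invalid boundary [{self.top}, {self.bottom}): need 0 <= top < bottom")

    @property
    def size(self) -> int:
        return self.bottom - self.top


def split_image(
    image: np.ndarray,
    boundaries: list[SplitBoundary | tuple[int, int]],
    axis: str = "row",
) -> list[np.ndarray]:
    """Split a multi-section scan into sub-images by verbatim cropping.

    Each boundary selects rows (``axis="row"``) or columns (``axis="column"``)
    ``[top, bottom)``; sub-images are bit-exact copies of the selected pixels.
    Boundaries must lie within the image and must not overlap each other.
    """
    image = validate_rgb(image)
    if axis not in ("row", "column"):
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    if not boundaries:
        raise ValueError("at least one boundary is required")
    bounds = [b if isinstance(b, SplitBoundary) else SplitBoundary(*b) for b in boundaries]
    extent = image.shape[0] if axis == "row" else image.shape[1]
    for b in bounds:
        if b.bottom > extent:
            raise ValueError(f"boundary [{b.top}, {b.bottom}) exceeds image extent {extent} along {axis}s")
    for a, b in zip(sorted(bounds, key=lambda x: x.top), sorted(bounds, key=lambda x: x.top)[1:]):
        if b.top < a.bottom:
            raise ValueError(f"boundaries [{a.top},{a.bottom}) and [{b.top},{b.bottom}) overlap")
    if axis == "row":
        return [image[b.top : b.bottom].copy() for b in bounds]
    return [image[:, b.top : b.bottom].copy() for b in bounds]


def auto_split_boundaries(
    image: np.ndarray,
    axis: str = "row",
    background_white_min: int = 230,
    min_gap: int = 2,
) -> list[SplitBoundary]:
    """Propose split boundaries by cutting at background valleys.

    Convenience helper beyond the interactive splitter it replaces: the tissue
    occupancy (any pixel with min(R,G,B) below ``background_white_min``) is
    projected onto the split axis; runs of occupied lines become sub-images and
    cuts are placed at the midpoints of the empty gaps between them.
    """
    image = validate_rgb(image)
    proj_axis = (1, 2) if axis == "row" else (0, 2)
    occupied = (image.min(axis=2, keepdims=True) < background_white_min).any(axis=proj_axis)
    occupied = np.asarray(occupied).ravel()
    runs: list[list[int]] = []
    for i, occ in enumerate(occupied):
        if occ and runs and runs[-1][1] == i:
            runs[-1][1] = i + 1
        elif occ:
            runs.append([i, i + 1])
    # merge runs separated by gaps narrower than min_gap (speckle tolerance)
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    if not merged:
        return []
    bounds = []
    n = len(occupied)
    for i, (start, stop) in enumerate(merged):
        top = 0 if i == 0 else (merged[i - 1][1] + start) // 2
        bottom = n if i == len(merged) - 1 else (stop + merged[i + 1][0]) // 2
        bounds.append(SplitBoundary(top, bottom))
    return bounds
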
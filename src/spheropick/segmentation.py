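"""Classical instance segmentation with shape filters.

Two pipelines are provided: global Otsu thresholding and marker-based
watershed on the distance transform. Both assume brightfield polarity
(objects darker than background; invertible via a flag), fill holes, label
8-connected components and then apply area/solidity/circularity filters to
discard debris and artifacts. A resize-to-1024 preprocessing transform with
aspect-ratio-preserving scaling and zero padding is provided for backends
that expect a fixed input size, together with its inverse for mapping
predicted masks back to the original frame.

Learned backends plug in through a registry keyed by name; they only need
to map a :class:`~spheropick.core.CalibratedImage` to a label mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure, segmentation as skseg, transform
from skimage.feature import peak_local_max

from .core import CalibratedImage, validate_label_mask, relabel_sequential
from .morphometrics import circularity as _circularity

TARGET_SIZE = 1024


@dataclass
class PreprocessTransform:
    """Invertible record of the resize-and-pad preprocessing step."""

    scale: float
    pad_rows: int
    pad_cols: int
    original_shape: tuple[int, int]


@dataclass
class ObjectFilterParams:
    """Bounds used to discard implausible objects after labeling.

    Defaults are fully permissive (keep everything).
    """

    min_area_px: float = 0.0
    max_area_px: float = math.inf
    min_solidity: float = 0.0
    min_circularity: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if not (0 <= self.min_solidity <= 1 and 0 <= self.min_circularity <= 1):
            raise ValueError("solidity/circularity bounds must lie in [0, 1]")


def resize_pad(image: CalibratedImage) -> tuple[CalibratedImage, PreprocessTransform]:
    """Downscale (or upscale) so the longer side is 1024 px, keeping aspect
    ratio, and zero-pad right/bottom to exactly 1024x1024.

    Content is anchored at the top-left corner. The pixel size is rescaled
    by 1/scale so physical measurements stay consistent.
    """
    gray = image.to_gray()
    h, w = gray.shape
    scale = TARGET_SIZE / max(h, w)
    new_h = round(h * scale)
    new_w = round(w * scale)
    resized = transform.resize(gray, (new_h, new_w), order=1,
                               anti_aliasing=scale < 1, preserve_range=True)
    out = np.zeros((TARGET_SIZE, TARGET_SIZE), dtype=np.float64)
    out[:new_h, :new_w] = resized
    t = PreprocessTransform(scale=scale, pad_rows=TARGET_SIZE - new_h,
                            pad_cols=TARGET_SIZE - new_w, original_shape=(h, w))
    return CalibratedImage(out, image.pixel_size_um / scale, image.stage_position_um), t


def unmap_mask(mask: np.ndarray, t: PreprocessTransform) -> np.ndarray:
    """Map a 1024x1024 label mask back to the original image frame.

    Strips the zero padding and rescales with nearest-neighbour
    interpolation so label identities are preserved exactly.
    """
    mask = validate_label_mask(mask)
    if mask.shape != (TARGET_SIZE, TARGET_SIZE):
        raise ValueError(f"mask must be {TARGET_SIZE}x{TARGET_SIZE}, got {mask.shape}")
    content = mask[:TARGET_SIZE - t.pad_rows, :TARGET_SIZE - t.pad_cols]
    if content.shape == t.original_shape:
        return content.astype(np.int32)
    out = transform.resize(content, t.original_shape, order=0,
                           anti_aliasing=False, preserve_range=True)
    return np.round(out).astype(np.int32)


def _otsu_foreground(image: CalibratedImage, smooth_sigma: float, invert: bool) -> np.ndarray:
    gray = image.to_gray()
    if np.ptp(gray) == 0:
        return np.zeros(gray.shape, dtype=bool)
    smoothed = ndimage.gaussian_filter(gray, smooth_sigma) if smooth_sigma > 0 else gray
    t = skfilters.threshold_otsu(smoothed)
    fg = smoothed > t if invert else smoothed < t
    return ndimage.binary_fill_holes(fg)


def segment_otsu(image: CalibratedImage, filters: ObjectFilterParams | None = None,
                 smooth_sigma: float = 2.0, invert: bool = False) -> np.ndarray:
    """Global Otsu threshold pipeline.

    Gaussian pre-smoothing (sigma in px) stabilises the threshold under
    noise; the darker side of the threshold is taken as foreground, holes
    are filled, 8-connected components labelled and shape filters applied.
    A constant image yields an empty mask.
    """
    filters = filters or ObjectFilterParams()
    fg = _otsu_foreground(image, smooth_sigma, invert)
    labeled = measure.label(fg, connectivity=2).astype(np.int32)
    return apply_object_filters(labeled, filters)


def segment_watershed(image: CalibratedImage, filters: ObjectFilterParams | None = None,
                      smooth_sigma: float = 2.0, invert: bool = False,
                      min_seed_distance: int = 10) -> np.ndarray:
    """Seeded watershed pipeline for splitting touching objects.

    The Otsu foreground is distance-transformed; local maxima of the
    distance map (separated by at least ``min_seed_distance`` px) seed a
    watershed on the negated distance map, so two objects merged by
    thresholding are split along their neck.
    """
    filters = filters or ObjectFilterParams()
    fg = _otsu_foreground(image, smooth_sigma, invert)
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    coords = peak_local_max(dist, min_distance=min_seed_distance, labels=fg)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labeled = measure.label(fg, connectivity=2).astype(np.int32)
    else:
        labeled = skseg.watershed(-dist, markers, mask=fg).astype(np.int32)
    return apply_object_filters(labeled, filters)


def apply_object_filters(mask: np.ndarray, filters: ObjectFilterParams) -> np.ndarray:
    """Remove objects outside the area/solidity/circularity bounds.

    Survivors are relabelled 1..m preserving ascending original label
    order. Idempotent.
    """
    mask = validate_label_mask(mask)
    if mask.max() == 0:
        return np.zeros_like(mask, dtype=np.int32)
    keep = np.zeros_like(mask, dtype=np.int32)
    for prop in measure.regionprops(mask):
        area = prop.area
        if not (filters.min_area_px <= area <= filters.max_area_px):
            continue
        if filters.min_solidity > 0 and prop.solidity < filters.min_solidity:
            continue
        if filters.min_circularity > 0:
            perim = prop.perimeter_crofton
            if perim <= 0 or _circularity(area, perim) < filters.min_circularity:
                continue
        keep[mask == prop.label] = prop.label
    return relabel_sequential(keep)


# ---------------------------------------------------------------------------
# pluggable segmenter registry

Segmenter = Callable[[CalibratedImage], np.ndarray]

_REGISTRY: dict[str, Segmenter] = {}


def register_segmenter(name: str, fn: Segmenter) -> None:
    """Register a segmentation backend under ``name``."""
    _REGISTRY[name] = fn


def run_segmenter(name: str, image: CalibratedImage, **kwargs) -> np.ndarray:
    """Run a registered backend and validate its output against the input."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown segmenter {name!r}; registered: {sorted(_REGISTRY)}")
    out = _REGISTRY[name](image, **kwargs)
    out = validate_label_mask(np.asarray(out), name=f"output of segmenter {name!r}")
    expected = image.to_gray().shape
    if out.shape != expected:
        raise ValueError(f"segmenter {name!r} returned shape {out.shape}, expected {expected}")
    return out


register_segmenter("otsu", segment_otsu)
register_segmenter("watershed", segment_watershed)
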
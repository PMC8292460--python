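"""Core containers shared across the toolkit."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibratedImage:
    """A 2D intensity raster with a physical pixel size.

    Parameters
    ----------
    data : ndarray
        2D grayscale (H, W) or RGB (H, W, 3) array. Grayscale data is kept
        as float in [0, 1]; integer input is rescaled on construction.
    pixel_size_um : float
        Physical size of one pixel edge in micrometres. Must be positive.
    stage_position_um : tuple of float, optional
        (x, y) stage coordinate of the image origin (pixel (0, 0)), in µm.
    """

    data: np.ndarray
    pixel_size_um: float
    stage_position_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or RGB, got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("image must be nonempty")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if np.issubdtype(self.data.dtype, np.integer):
            info = np.iinfo(self.data.dtype)
            self.data = self.data.astype(np.float64) / info.max

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def to_gray(self) -> np.ndarray:
        """Return a 2D float array; RGB is reduced by Rec. 601 luminance."""
        if self.data.ndim == 2:
            return self.data
        w = np.array([0.299, 0.587, 0.114])
        return self.data[..., :3] @ w


def validate_label_mask(mask: np.ndarray, *, name: str = "mask") -> np.ndarray:
    """Check that ``mask`` is a 2D integer label image (0 = background)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"{name} must have integer dtype, got {mask.dtype}")
    if mask.size and mask.min() < 0:
        raise ValueError(f"{name} contains negative labels")
    return mask


def relabel_sequential(mask: np.ndarray) -> np.ndarray:
    """Relabel objects 1..n preserving the ascending order of original ids."""
    mask = validate_label_mask(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask, dtype=np.int32)
    for new, old in enumerate(labels, start=1):
        out[mask == old] = new
    return out


@dataclass
class RunLog:
    """Append-only structured log written as JSON lines."""

    path: object = None
    records: list = field(default_factory=list)

    def log(self, **fields) -> None:
        import json
        import time

        rec = {"t": time.time(), **fields}
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
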
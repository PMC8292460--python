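"""Per-object morphometric features in physical units.

Features follow the conventions of standard spheroid morphology software:
area and perimeter calibrated by the pixel size, ISO-style circularity
4·π·A/P² (1 for a perfect circle), equivalent diameter 2·√(A/π), solidity
as area over convex-hull area, and a sphere-equivalent volume estimate
(π/6)·d_eq³ flagged as such in output metadata. The perimeter uses the
Crofton estimator rather than a boundary-pixel count: pixel counting
systematically overestimates the perimeter of smooth shapes and would push
the circularity of true circles far below 1, making circularity thresholds
around 0.8 meaningless.

Coordinates are (row, col), 0-based, with pixel centres at integer
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage import measure

from .core import validate_label_mask

VOLUME_METHOD = "sphere_equivalent"

#: numeric feature columns, in output order
FEATURE_COLUMNS = (
    "label", "area_um2", "perimeter_um", "circularity",
    "equivalent_diameter_um", "solidity", "volume_um3",
    "centroid_row", "centroid_col", "stage_x_um", "stage_y_um",
)


@dataclass
class SpheroidRecord:
    """Morphometric feature vector of one segmented spheroid."""

    label: int
    area_um2: float
    perimeter_um: float
    circularity: float
    equivalent_diameter_um: float
    solidity: float
    volume_um3: float
    centroid_px: tuple[float, float]
    bbox_px: tuple[int, int, int, int]
    stage_um: tuple[float, float] | None = None

    def feature(self, name: str) -> float:
        """Look up a scalar feature by name (for criteria evaluation)."""
        if name not in _SCALAR_FEATURES:
            raise KeyError(f"unknown feature {name!r}; known: {sorted(_SCALAR_FEATURES)}")
        return getattr(self, name)


_SCALAR_FEATURES = {
    "area_um2", "perimeter_um", "circularity",
    "equivalent_diameter_um", "solidity", "volume_um3",
}


def circularity(area: float, perimeter: float) -> float:
    """ISO-style roundness 4·π·area/perimeter², clamped to 1.

    Equals 1 for an ideal circle and decreases with boundary irregularity.
    Units cancel, so pixel or physical units may be used consistently.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(4.0 * math.pi * area / perimeter**2, 1.0)


def equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the same area: 2·sqrt(A/π)."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def volume_estimate(area_um2: float) -> float:
    """Sphere-equivalent volume (π/6)·d_eq³ from the projected 2D area."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    d = equivalent_diameter(area_um2)
    return math.pi / 6.0 * d**3


def solidity(mask_object: np.ndarray) -> float:
    """Pixel area over convex-hull area for a single binary object."""
    obj = np.asarray(mask_object).astype(bool)
    if not obj.any():
        raise ValueError("object is empty")
    props = measure.regionprops(obj.astype(np.uint8))
    return float(props[0].solidity)


def extract_features(mask: np.ndarray, pixel_size_um: float,
                     stage_origin_um: tuple[float, float] | None = None) -> list[SpheroidRecord]:
    """Compute one SpheroidRecord per label, in ascending label order.

    ``stage_origin_um`` is the (x, y) stage coordinate of pixel (0, 0); when
    given, each record carries the stage coordinate of its mass centre
    (x along columns, y along rows).
    """
    mask = validate_label_mask(mask)
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    records: list[SpheroidRecord] = []
    for prop in measure.regionprops(mask):
        area_um2 = prop.area * pixel_size_um**2
        perimeter_um = max(prop.perimeter_crofton, 1e-12) * pixel_size_um
        stage = None
        if stage_origin_um is not None:
            stage = (stage_origin_um[0] + prop.centroid[1] * pixel_size_um,
                     stage_origin_um[1] + prop.centroid[0] * pixel_size_um)
        records.append(SpheroidRecord(
            label=int(prop.label),
            area_um2=float(area_um2),
            perimeter_um=float(perimeter_um),
            circularity=circularity(area_um2, perimeter_um),
            equivalent_diameter_um=equivalent_diameter(area_um2),
            solidity=float(prop.solidity),
            volume_um3=volume_estimate(area_um2),
            centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
            bbox_px=tuple(int(v) for v in prop.bbox),
            stage_um=stage,
        ))
    return records


def records_to_dataframe(records: list[SpheroidRecord]) -> pd.DataFrame:
    """Flatten records into the canonical feature table."""
    rows = []
    for r in records:
        d = asdict(r)
        d["centroid_row"], d["centroid_col"] = d.pop("centroid_px")
        stage = d.pop("stage_um")
        d["stage_x_um"], d["stage_y_um"] = stage if stage is not None else (np.nan, np.nan)
        d.pop("bbox_px")
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return df


def records_from_dataframe(df: pd.DataFrame) -> list[SpheroidRecord]:
    """Rebuild records from a feature table (bbox is not round-tripped)."""
    records = []
    for _, row in df.iterrows():
        stage = None
        if "stage_x_um" in row and not pd.isna(row["stage_x_um"]):
            stage = (float(row["stage_x_um"]), float(row["stage_y_um"]))
        records.append(SpheroidRecord(
            label=int(row["label"]),
            area_um2=float(row["area_um2"]),
            perimeter_um=float(row["perimeter_um"]),
            circularity=float(row["circularity"]),
            equivalent_diameter_um=float(row["equivalent_diameter_um"]),
            solidity=float(row["solidity"]),
            volume_um3=float(row["volume_um3"]),
            centroid_px=(float(row.get("centroid_row", np.nan)), float(row.get("centroid_col", np.nan))),
            bbox_px=(0, 0, 0, 0),
            stage_um=stage,
        ))
    return records
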
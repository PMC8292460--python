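"""Reading and writing images, masks, feature tables and annotations."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .core import CalibratedImage, validate_label_mask
from .simulate import SceneSpec, ObjectSpec, ArtifactSpec


def save_image(image: CalibratedImage, path) -> None:
    """Write a calibrated image: 16-bit grayscale TIFF or 8-bit PNG by
    file extension; the pixel size is recorded in TIFF metadata."""
    path = Path(path)
    gray = np.clip(image.to_gray(), 0, 1)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = (gray * 65535).round().astype(np.uint16)
        tifffile.imwrite(path, data, metadata={"pixel_size_um": image.pixel_size_um})
    elif path.suffix.lower() == ".png":
        data = (gray * 255).round().astype(np.uint8)
        Image.fromarray(data).save(path)
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")


def load_image(path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read a PNG/TIFF image; pixel size from TIFF metadata unless given."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            if pixel_size_um is None:
                meta = tf.shaped_metadata or tf.imagej_metadata or ({},)
                meta = meta[0] if isinstance(meta, tuple) else meta
                pixel_size_um = float(meta.get("pixel_size_um", 1.0)) if meta else 1.0
    else:
        data = np.asarray(Image.open(path))
        if pixel_size_um is None:
            pixel_size_um = 1.0
    return CalibratedImage(data, pixel_size_um)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a label mask as 16-bit TIFF."""
    mask = validate_label_mask(mask)
    if mask.max() > 65535:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def load_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def save_features(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)


def load_features(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


# --- SceneSpec JSON round trip ---------------------------------------------

def scene_spec_to_json(spec: SceneSpec) -> dict:
    return dataclasses.asdict(spec)


def scene_spec_from_json(data: dict | str) -> SceneSpec:
    if isinstance(data, str):
        data = json.loads(data)
    objects = [ObjectSpec(center_px=tuple(o["center_px"]), radius_px=o["radius_px"],
                          irregularity=[tuple(t) for t in o.get("irregularity", [])],
                          interior_level=o.get("interior_level", 0.55),
                          halo_gain=o.get("halo_gain", 0.1),
                          defocus_sigma_px=o.get("defocus_sigma_px", 0.0))
               for o in data.get("objects", [])]
    artifacts = [ArtifactSpec(kind=a["kind"], params=a.get("params", {}))
                 for a in data.get("artifacts", [])]
    return SceneSpec(
        image_shape_px=tuple(data.get("image_shape_px", (512, 512))),
        pixel_size_um=data.get("pixel_size_um", 2.0),
        background_level=data.get("background_level", 0.75),
        illumination_gradient=tuple(data.get("illumination_gradient", (0.0, 0.0))),
        noise_sigma=data.get("noise_sigma", 0.0),
        objects=objects,
        artifacts=artifacts,
        seed=data.get("seed", 0),
    )


# --- COCO-style annotation export ------------------------------------------

def mask_to_coco(mask: np.ndarray, image_id: int = 1, category_id: int = 1) -> dict:
    """Export a label mask as a minimal COCO-style annotation dict with
    polygon segmentations (one polygon per object contour)."""
    from skimage import measure as skmeasure

    mask = validate_label_mask(mask)
    h, w = mask.shape
    annotations = []
    for label in np.unique(mask):
        if label == 0:
            continue
        binary = (mask == label)
        ys, xs = np.nonzero(binary)
        bbox = [float(xs.min()), float(ys.min()),
                float(xs.max() - xs.min() + 1), float(ys.max() - ys.min() + 1)]
        contours = skmeasure.find_contours(binary.astype(float), 0.5)
        segmentation = []
        for contour in contours:
            poly = []
            for r, c in contour:
                poly += [float(c), float(r)]  # COCO order: x, y
            if len(poly) >= 6:
                segmentation.append(poly)
        annotations.append({
            "id": int(label), "image_id": image_id, "category_id": category_id,
            "bbox": bbox, "area": float(binary.sum()),
            "segmentation": segmentation, "iscrowd": 0,
        })
    return {
        "images": [{"id": image_id, "height": h, "width": w}],
        "categories": [{"id": category_id, "name": "spheroid"}],
        "annotations": annotations,
    }
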
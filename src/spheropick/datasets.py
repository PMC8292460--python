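"""Dataset bookkeeping and the end-to-end pipeline runner.

Train/validation/test assignment is per image — every object inherits its
image's split — which prevents leakage of near-duplicate objects across
splits. The default fractions are 70/15/15 with largest-remainder rounding
so small datasets still use every image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SPLITS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class DatasetManifest:
    """Per-image split assignment, reproducible from the seed."""

    entries: list[tuple[str, str, str]]  # (image_path, mask_path, split)
    fractions: tuple[float, float, float]
    seed: int

    def paths(self, split: str) -> list[tuple[str, str]]:
        if split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        return [(img, msk) for img, msk, s in self.entries if s == split]

    def to_json(self, path=None) -> str:
        text = json.dumps({"entries": self.entries, "fractions": self.fractions,
                           "seed": self.seed}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DatasetManifest":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(entries=[tuple(e) for e in data["entries"]],
                   fractions=tuple(data["fractions"]), seed=data["seed"])


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    exact = [n * f for f in fractions]
    base = [math.floor(x) for x in exact]
    short = n - sum(base)
    # ties broken by split order (train before val before test)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(entries, fractions=DEFAULT_FRACTIONS, seed: int = 0) -> DatasetManifest:
    """Assign (image, mask) entries to train/val/test splits.

    A seeded shuffle is followed by contiguous assignment sized by
    largest-remainder rounding of the fractions; identical seeds give
    identical manifests.
    """
    entries = [tuple(e) for e in entries]
    if len(entries) < 3:
        raise ValueError("need at least 3 entries to split")
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need 3 positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    counts = _largest_remainder_counts(len(entries), fractions)
    assigned = []
    pos = 0
    for split, count in zip(SPLITS, counts):
        for idx in order[pos:pos + count]:
            img, msk = entries[idx][:2]
            assigned.append((img, msk, split))
        pos += count
    return DatasetManifest(entries=assigned, fractions=tuple(fractions), seed=seed)


# --- pipeline runner -------------------------------------------------------

_KNOWN_STAGES = ("simulate", "segment", "features", "select", "evaluate")

_SCHEMA = {
    "simulate": {"n_images", "profile", "image_shape_px", "pixel_size_um"},
    "segment": {"method", "filters"},
    "features": set(),
    "select": {"criteria"},
    "evaluate": {"taus"},
}


def validate_config(config: dict) -> None:
    """Validate a pipeline config before any work is done."""
    if "stages" not in config or not isinstance(config["stages"], dict):
        raise ValueError("config must contain a 'stages' mapping")
    for stage, params in config["stages"].items():
        if stage not in _KNOWN_STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {_KNOWN_STAGES}")
        unknown = set(params) - _SCHEMA[stage]
        if unknown:
            raise ValueError(f"stage {stage!r}: unknown keys {sorted(unknown)}")


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the configured stages and write artifacts under ``out_dir``.

    Stages run in the fixed order simulate → segment → features → select →
    evaluate; each writes its outputs to disk and a JSON-lines run log
    records seeds and parameters. Returns a dict of in-memory results.
    """
    from . import io as spio
    from .core import RunLog
    from .evaluation import evaluate_dataset, DEFAULT_TAU_GRID
    from .morphometrics import extract_features, records_to_dataframe
    from .segmentation import ObjectFilterParams, run_segmenter
    from .selection import SelectionCriteria, apply_criteria
    from .simulate import make_benchmark_set

    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(path=out_dir / "run_log.jsonl")
    log.log(event="start", seed=seed, config=config)
    stages = config["stages"]
    results: dict = {}

    if "simulate" in stages:
        p = stages["simulate"]
        pairs = make_benchmark_set(
            p.get("n_images", 20), p.get("profile", "default"), seed,
            tuple(p.get("image_shape_px", (512, 512))), p.get("pixel_size_um", 2.0))
        results["dataset"] = pairs
        for i, (img, msk) in enumerate(pairs):
            spio.save_image(img, out_dir / f"image_{i:03d}.tif")
            spio.save_mask(msk, out_dir / f"mask_{i:03d}.tif")
        log.log(event="simulate", n_images=len(pairs), profile=p.get("profile", "default"))

    if "segment" in stages:
        p = stages["segment"]
        method = p.get("method", "otsu")
        filt = ObjectFilterParams(**p.get("filters", {}))
        preds = [run_segmenter(method, img, filters=filt) for img, _ in results["dataset"]]
        results["predictions"] = preds
        for i, pred in enumerate(preds):
            spio.save_mask(pred, out_dir / f"pred_{i:03d}.tif")
        log.log(event="segment", method=method)

    if "features" in stages:
        frames = []
        records_all = []
        for i, (img, _) in enumerate(results["dataset"]):
            recs = extract_features(results["predictions"][i], img.pixel_size_um)
            records_all.extend(recs)
            df = records_to_dataframe(recs)
            df.insert(0, "image", i)
            frames.append(df)
        import pandas as pd

        table = pd.concat(frames, ignore_index=True) if frames else None
        results["features"] = records_all
        if table is not None:
            spio.save_features(table, out_dir / "features.csv")
        log.log(event="features", n_objects=len(records_all))

    if "select" in stages:
        criteria = SelectionCriteria.from_json(stages["select"].get("criteria", {}))
        report = apply_criteria(results["features"], criteria)
        results["selection"] = report
        (out_dir / "selection.json").write_text(json.dumps({
            "n_selected": len(report.selected),
            "n_rejected": len(report.rejected),
            "summary": {k: list(v) for k, v in report.summary.items()},
        }, indent=2))
        log.log(event="select", n_selected=len(report.selected))

    if "evaluate" in stages:
        taus = stages["evaluate"].get("taus", list(DEFAULT_TAU_GRID))
        pairs = [(pred, gt) for pred, (_, gt) in zip(results["predictions"], results["dataset"])]
        ev = evaluate_dataset(pairs, taus)
        results["evaluation"] = ev
        import pandas as pd

        rows = [{"tau": t, "precision": p, "sensitivity": s,
                 "tp": c.tp, "fp": c.fp, "fn": c.fn}
                for (t, p, s), c in zip(ev.pooled.points, ev.pooled.counts)]
        pd.DataFrame(rows).to_csv(out_dir / "evaluation.csv", index=False)
        log.log(event="evaluate", taus=list(taus))

    log.log(event="done")
    return results
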
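"""Criterion-based spheroid selection and summary statistics.

An operator states per-feature closed intervals (e.g. area between 21,000
and 29,000 µm² and circularity at least 0.815); a record is selected iff
every bounded interval contains its value. Interval bounds are inclusive,
so an object with circularity exactly at the stated minimum passes. An
optional preferred value ranks the selected set by ascending distance to a
target (ties broken by label id); an optional cap truncates after ranking.
Summary statistics use the sample standard deviation (n−1), matching how
replicate spheroid batches are normally reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .morphometrics import SpheroidRecord, _SCALAR_FEATURES

#: feature order used when reporting the first failed criterion
_REJECT_ORDER_HEAD = ("area_um2", "circularity")


@dataclass
class SelectionCriteria:
    """Per-feature closed intervals plus optional ranking and cap."""

    intervals: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    preferred_value: tuple[str, float] | None = None
    max_count: int | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"criterion {name!r}: min {lo} > max {hi}")
        if self.max_count is not None and self.max_count < 0:
            raise ValueError("max_count must be nonnegative")

    @classmethod
    def from_json(cls, source) -> "SelectionCriteria":
        """Parse criteria from a JSON mapping, string or file path.

        Format: {"area_um2": {"min": 21000, "max": 29000},
                 "circularity": {"min": 0.815},
                 "preferred": {"feature": "area_um2", "value": 25000},
                 "max_count": 10}
        """
        if isinstance(source, dict):
            data = dict(source)
        else:
            text = source.read_text() if hasattr(source, "read_text") else str(source)
            data = json.loads(text)
        intervals = {}
        preferred = None
        max_count = data.pop("max_count", None) if isinstance(data, dict) else None
        for name, spec in data.items():
            if name == "preferred":
                preferred = (spec["feature"], float(spec["value"]))
            else:
                intervals[name] = (spec.get("min"), spec.get("max"))
        return cls(intervals=intervals, preferred_value=preferred, max_count=max_count)


@dataclass
class SelectionReport:
    """Outcome of applying criteria: ordered selection, per-record rejection
    reasons, and per-feature mean/SD of the selected set."""

    selected: list[SpheroidRecord]
    rejected: list[tuple[SpheroidRecord, str]]
    summary: dict[str, tuple[float, float]]


def _criterion_order(intervals: dict) -> list[str]:
    head = [f for f in _REJECT_ORDER_HEAD if f in intervals]
    tail = sorted(f for f in intervals if f not in _REJECT_ORDER_HEAD)
    return head + tail


def apply_criteria(records: list[SpheroidRecord], criteria: SelectionCriteria) -> SelectionReport:
    """Partition records into selected/rejected under the criteria.

    Selection order is input order unless a preferred value is set, in
    which case selected records are ranked by |feature − target| ascending.
    Empty criteria select everything.
    """
    for name in criteria.intervals:
        if name not in _SCALAR_FEATURES:
            raise KeyError(f"unknown feature {name!r}; known: {sorted(_SCALAR_FEATURES)}")
    if criteria.preferred_value is not None and criteria.preferred_value[0] not in _SCALAR_FEATURES:
        raise KeyError(f"unknown feature {criteria.preferred_value[0]!r}; "
                       f"known: {sorted(_SCALAR_FEATURES)}")

    order = _criterion_order(criteria.intervals)
    selected: list[SpheroidRecord] = []
    rejected: list[tuple[SpheroidRecord, str]] = []
    for rec in records:
        reason = None
        for name in order:
            lo, hi = criteria.intervals[name]
            v = rec.feature(name)
            if lo is not None and v < lo:
                reason = f"{name} < {lo}"
                break
            if hi is not None and v > hi:
                reason = f"{name} > {hi}"
                break
        if reason is None:
            selected.append(rec)
        else:
            rejected.append((rec, reason))

    if criteria.preferred_value is not None:
        feat, target = criteria.preferred_value
        selected.sort(key=lambda r: (abs(r.feature(feat) - target), r.label))
    if criteria.max_count is not None and len(selected) > criteria.max_count:
        for rec in selected[criteria.max_count:]:
            rejected.append((rec, f"max_count {criteria.max_count} exceeded"))
        selected = selected[:criteria.max_count]

    summary = {}
    if selected:
        for name in sorted(_SCALAR_FEATURES):
            mean, sd, _n = summarize(selected, name)
            summary[name] = (mean, sd)
    return SelectionReport(selected=selected, rejected=rejected, summary=summary)


def summarize(records, feature: str | None = None) -> tuple[float, float, int]:
    """Arithmetic mean and sample SD (n−1) of a feature over records.

    ``records`` may be SpheroidRecords (with ``feature`` naming the field)
    or a plain sequence of numbers. A single value reports SD 0.
    """
    if feature is not None:
        values = np.array([r.feature(feature) for r in records], dtype=float)
    else:
        values = np.asarray(list(records), dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("cannot summarize an empty set")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n >= 2 else 0.0
    return mean, sd, n


def sd_ratio(sd_a: float, sd_b: float) -> float:
    """Ratio of two standard deviations, reported to 3 decimals."""
    if sd_b <= 0:
        raise ValueError("denominator SD must be positive")
    return round(sd_a / sd_b, 3)
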
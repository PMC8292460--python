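"""Virtual instrument layer: plates, calibration, scanning and transfer.

Models the motion side of an automated spheroid picker: ANSI/SLAS
microplate geometry, the image-to-stage calibration that maps a pixel
under the camera to a stage displacement, serpentine scan tiling of wells,
and transfer-plan generation. A transfer moves the stage so the chosen
spheroid sits under the capillary tip, lowers the pipette, aspirates
3–4 µl of medium together with the spheroid, raises the pipette, moves the
target well under the objective, and dispenses. Plans are emitted as
Marlin-dialect G-code for the pipette axes and the syringe (extruder
axis); stage motions ride a separate controller and are therefore emitted
as structured comments rather than an invented protocol.

Transfer outcomes are tallied into success statistics over the closed
failure taxonomy: pick-up error (failed intake or loss in transit), expel
error (failure to release into the target well) and double pick
(unintended capture of a second spheroid).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field

OUTCOMES = ("success", "pick_up_error", "expel_error", "double_pick")

#: default aspiration volume bounds in µl ("soaks up about 3–4 µl")
DEFAULT_VOLUME_BOUNDS = (3.0, 4.0)
DEFAULT_VOLUME_UL = 3.5
#: syringe resolution metadata, µl (recorded, not enforced)
SYRINGE_RESOLUTION_UL = 3.0


@dataclass
class PlateLayout:
    """Rectangular well-plate geometry in the SLAS convention.

    a1_offset_mm is the (x, y) position of well A1's centre from the plate
    origin (top-left corner); wells advance by ``pitch_mm`` along columns
    (x) and rows (y).
    """

    name: str
    rows: int
    cols: int
    pitch_mm: float
    a1_offset_mm: tuple[float, float]
    well_diameter_mm: float
    footprint_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        x_extent = self.a1_offset_mm[0] + (self.cols - 1) * self.pitch_mm + self.well_diameter_mm / 2
        y_extent = self.a1_offset_mm[1] + (self.rows - 1) * self.pitch_mm + self.well_diameter_mm / 2
        if x_extent > self.footprint_mm[0] or y_extent > self.footprint_mm[1]:
            raise ValueError(f"wells of {self.name!r} extend beyond the plate footprint")

    def well_ids(self) -> list[str]:
        return [f"{chr(ord('A') + r)}{c + 1}" for r in range(self.rows) for c in range(self.cols)]


#: ANSI/SLAS default geometries (footprint 127.76 x 85.48 mm)
PLATE_LAYOUTS: dict[str, PlateLayout] = {
    "96well": PlateLayout("96well", rows=8, cols=12, pitch_mm=9.0,
                          a1_offset_mm=(14.38, 11.24), well_diameter_mm=6.96,
                          footprint_mm=(127.76, 85.48)),
    "384well": PlateLayout("384well", rows=16, cols=24, pitch_mm=4.5,
                           a1_offset_mm=(12.13, 8.99), well_diameter_mm=3.3,
                           footprint_mm=(127.76, 85.48)),
    "24well": PlateLayout("24well", rows=4, cols=6, pitch_mm=19.3,
                          a1_offset_mm=(15.63, 13.79), well_diameter_mm=15.6,
                          footprint_mm=(127.76, 85.48)),
}

_WELL_RE = re.compile(r"^([A-Z]+)(\d+)$")


def parse_well_id(layout: PlateLayout, well_id: str) -> tuple[int, int]:
    """Parse "B7" into 1-based (row, col); errors name the valid bounds."""
    m = _WELL_RE.match(well_id.strip().upper())
    if not m:
        raise ValueError(f"malformed well id {well_id!r}")
    letters, digits = m.groups()
    row = 0
    for ch in letters:
        row = row * 26 + (ord(ch) - ord("A") + 1)
    col = int(digits)
    if not (1 <= row <= layout.rows and 1 <= col <= layout.cols):
        raise ValueError(
            f"well {well_id!r} outside plate {layout.name!r} "
            f"(rows A..{chr(ord('A') + layout.rows - 1)}, cols 1..{layout.cols})")
    return row, col


def well_center(layout: PlateLayout, well_id: str) -> tuple[float, float]:
    """(x, y) centre of a well in plate coordinates, mm."""
    row, col = parse_well_id(layout, well_id)
    return (layout.a1_offset_mm[0] + (col - 1) * layout.pitch_mm,
            layout.a1_offset_mm[1] + (row - 1) * layout.pitch_mm)


@dataclass
class Calibration:
    """Image-to-stage mapping established by jogging the capillary tip to a
    known pixel and registering the coordinates."""

    tip_px: tuple[float, float]
    z_min_mm: float
    um_per_px: float
    axis_sign: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.um_per_px is None or self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.tip_px is None or self.z_min_mm is None:
            raise ValueError("calibration incomplete: tip_px and z_min_mm are required")
        if tuple(abs(s) for s in self.axis_sign) != (1, 1):
            raise ValueError("axis_sign components must be +1 or -1")


def image_to_stage(cal: Calibration, object_px: tuple[float, float],
                   current_stage_mm: tuple[float, float]) -> tuple[float, float]:
    """Stage target that brings ``object_px`` under the capillary tip.

    Pixel columns map to stage x and rows to stage y, each flipped by the
    calibrated axis sign; displacement is converted from µm to mm.
    """
    dr = object_px[0] - cal.tip_px[0]
    dc = object_px[1] - cal.tip_px[1]
    dx_mm = cal.axis_sign[0] * dc * cal.um_per_px / 1000.0
    dy_mm = cal.axis_sign[1] * dr * cal.um_per_px / 1000.0
    return (current_stage_mm[0] + dx_mm, current_stage_mm[1] + dy_mm)


def stage_to_image(cal: Calibration, stage_target_mm: tuple[float, float],
                   current_stage_mm: tuple[float, float]) -> tuple[float, float]:
    """Inverse of :func:`image_to_stage` (pixel that a stage move centres)."""
    dx_mm = stage_target_mm[0] - current_stage_mm[0]
    dy_mm = stage_target_mm[1] - current_stage_mm[1]
    dc = cal.axis_sign[0] * dx_mm * 1000.0 / cal.um_per_px
    dr = cal.axis_sign[1] * dy_mm * 1000.0 / cal.um_per_px
    return (cal.tip_px[0] + dr, cal.tip_px[1] + dc)


def plan_scan(layout: PlateLayout, wells: list[str], fov_mm: tuple[float, float],
              overlap_fraction: float = 0.0) -> list[tuple[float, float]]:
    """Serpentine grid of stage positions covering each well's bounding
    square with step fov·(1−overlap); every well point is covered by at
    least one tile. Wells are visited in the given order.
    """
    if fov_mm[0] <= 0 or fov_mm[1] <= 0:
        raise ValueError("fov must be positive")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    positions: list[tuple[float, float]] = []
    for well in wells:
        cx, cy = well_center(layout, well)
        extent = layout.well_diameter_mm
        tiles_axis = []
        for fov, c in ((fov_mm[0], cx), (fov_mm[1], cy)):
            if extent <= fov:
                tiles_axis.append([c])
                continue
            step = fov * (1 - overlap_fraction)
            n = math.ceil((extent - fov) / step) + 1
            start = c - extent / 2 + fov / 2
            tiles_axis.append([start + i * step for i in range(n)])
        xs, ys = tiles_axis
        for j, y in enumerate(ys):
            row = xs if j % 2 == 0 else list(reversed(xs))
            positions.extend((x, y) for x in row)
    return positions


# --- transfer plan ---------------------------------------------------------

@dataclass
class MoveStage:
    x_mm: float
    y_mm: float


@dataclass
class PipetteX:
    mm: float


@dataclass
class PipetteZ:
    mm: float


@dataclass
class Aspirate:
    ul: float


@dataclass
class Dispense:
    ul: float


Command = MoveStage | PipetteX | PipetteZ | Aspirate | Dispense


@dataclass
class TransferPlan:
    """Ordered abstract instrument commands plus per-spheroid metadata."""

    commands: list[Command]
    metadata: list[dict] = field(default_factory=list)
    z_min_mm: float = 0.0
    volume_bounds_ul: tuple[float, float] = DEFAULT_VOLUME_BOUNDS


def validate_plan(plan: TransferPlan) -> None:
    """Assert the structural safety invariants of a plan.

    Per spheroid exactly one Aspirate then one Dispense; aspiration volume
    within bounds; the pipette never commanded below z_min; every
    Aspirate/Dispense issued while the pipette sits at or above z_min.
    """
    z = None
    open_aspirations = 0
    n_asp = n_disp = 0
    lo, hi = plan.volume_bounds_ul
    for cmd in plan.commands:
        if isinstance(cmd, PipetteZ):
            if cmd.mm < plan.z_min_mm:
                raise ValueError(f"PipetteZ {cmd.mm} below z_min {plan.z_min_mm}")
            z = cmd.mm
        elif isinstance(cmd, Aspirate):
            if z is None or z < plan.z_min_mm:
                raise ValueError("Aspirate before a valid PipetteZ")
            if not (lo <= cmd.ul <= hi):
                raise ValueError(f"aspirate volume {cmd.ul} outside bounds [{lo}, {hi}] µl")
            if open_aspirations:
                raise ValueError("second Aspirate before Dispense")
            open_aspirations += 1
            n_asp += 1
        elif isinstance(cmd, Dispense):
            if z is None or z < plan.z_min_mm:
                raise ValueError("Dispense before a valid PipetteZ")
            if not open_aspirations:
                raise ValueError("Dispense without a preceding Aspirate")
            open_aspirations -= 1
            n_disp += 1
    if open_aspirations:
        raise ValueError("plan ends with an open aspiration")
    if n_asp != len(plan.metadata) or n_disp != len(plan.metadata):
        raise ValueError("aspirate/dispense count does not match planned spheroids")


def plan_transfer(selected, target_layout: PlateLayout, target_wells: list[str],
                  cal: Calibration, volume_ul: float = DEFAULT_VOLUME_UL,
                  volume_bounds_ul: tuple[float, float] = DEFAULT_VOLUME_BOUNDS,
                  pipette_x_work_mm: float = 50.0, pipette_x_rest_mm: float = 0.0,
                  z_travel_mm: float | None = None,
                  target_plate_origin_mm: tuple[float, float] = (0.0, 0.0)) -> TransferPlan:
    """Build the command sequence transferring each selected spheroid to a
    target well, ending with a pipette retraction out of the field of view.

    Each record in ``selected`` must carry a stage coordinate (stage_um).
    """
    lo, hi = volume_bounds_ul
    if not (lo <= volume_ul <= hi):
        raise ValueError(f"volume {volume_ul} µl outside bounds [{lo}, {hi}] µl")
    if len(target_wells) < len(selected):
        raise ValueError(f"{len(selected)} spheroids but only {len(target_wells)} target wells")
    z_up = z_travel_mm if z_travel_mm is not None else cal.z_min_mm + 5.0

    commands: list[Command] = []
    metadata: list[dict] = []
    for rec, well in zip(selected, target_wells):
        if getattr(rec, "stage_um", None) is None:
            raise ValueError(f"spheroid label {getattr(rec, 'label', '?')} has no stage coordinates")
        src_mm = (rec.stage_um[0] / 1000.0, rec.stage_um[1] / 1000.0)
        wx, wy = well_center(target_layout, well)
        tgt_mm = (target_plate_origin_mm[0] + wx, target_plate_origin_mm[1] + wy)
        commands += [
            MoveStage(*src_mm),
            PipetteX(pipette_x_work_mm),
            PipetteZ(cal.z_min_mm),
            Aspirate(volume_ul),
            PipetteZ(z_up),
            MoveStage(*tgt_mm),
            PipetteZ(cal.z_min_mm),
            Dispense(volume_ul),
            PipetteZ(z_up),
        ]
        metadata.append({"label": getattr(rec, "label", None),
                         "source_stage_mm": src_mm, "target_well": well})
    commands.append(PipetteX(pipette_x_rest_mm))  # retract out of the field of view
    plan = TransferPlan(commands=commands, metadata=metadata,
                        z_min_mm=cal.z_min_mm, volume_bounds_ul=volume_bounds_ul)
    validate_plan(plan)
    return plan


# --- G-code emission -------------------------------------------------------

@dataclass
class MotionConfig:
    """Feed rates (mm/min) and the syringe volume-to-axis conversion."""

    feed_x_mm_min: float = 1200.0
    feed_z_mm_min: float = 600.0
    feed_e_mm_min: float = 120.0
    ul_to_mm: float | None = 0.5


def emit_gcode(plan: TransferPlan, config: MotionConfig | None = None) -> str:
    """Render a plan as Marlin-dialect G-code text.

    Pipette X/Z map to ``G1 X../Z..`` moves; aspirate/dispense map to
    relative extruder moves (negative E = intake); stage motions are
    emitted as ``;STAGE`` comments because the stage rides a separate
    controller. Deterministic for a given plan and config.
    """
    config = config or MotionConfig()
    if config.ul_to_mm is None:
        raise ValueError("MotionConfig.ul_to_mm is required to emit syringe moves")
    lines = [
        "; spheropick transfer plan",
        f"; spheroids: {len(plan.metadata)}",
        "G21 ; millimetre units",
        "G90 ; absolute positioning",
        "M83 ; relative extruder (syringe)",
        "G28 X Z ; home pipette axes",
    ]
    for cmd in plan.commands:
        if isinstance(cmd, MoveStage):
            lines.append(f";STAGE MOVE X{cmd.x_mm:.3f} Y{cmd.y_mm:.3f}")
        elif isinstance(cmd, PipetteX):
            lines.append(f"G1 X{cmd.mm:.3f} F{config.feed_x_mm_min:.0f}")
        elif isinstance(cmd, PipetteZ):
            lines.append(f"G1 Z{cmd.mm:.3f} F{config.feed_z_mm_min:.0f}")
        elif isinstance(cmd, Aspirate):
            lines.append(f"G1 E-{cmd.ul * config.ul_to_mm:.3f} F{config.feed_e_mm_min:.0f}")
        elif isinstance(cmd, Dispense):
            lines.append(f"G1 E{cmd.ul * config.ul_to_mm:.3f} F{config.feed_e_mm_min:.0f}")
        else:  # pragma: no cover
            raise TypeError(f"unknown command {cmd!r}")
    lines.append("; end of transfer session")
    return "\n".join(lines) + "\n"


# --- transfer outcome statistics -------------------------------------------

@dataclass
class TransferAttempt:
    object_id: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome {self.outcome!r} not in {OUTCOMES}")


@dataclass
class TransferLog:
    attempts: list[TransferAttempt]

    @classmethod
    def from_csv(cls, path) -> "TransferLog":
        attempts = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                attempts.append(TransferAttempt(row["object_id"], row["outcome"]))
        return cls(attempts)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["object_id", "outcome"])
            for a in self.attempts:
                writer.writerow([a.object_id, a.outcome])


def success_stats(log: TransferLog) -> dict:
    """Tally attempt outcomes into a success rate (nearest integer percent)
    and per-failure-mode counts."""
    if not log.attempts:
        raise ValueError("transfer log is empty")
    counts = {k: 0 for k in OUTCOMES}
    for a in log.attempts:
        counts[a.outcome] += 1
    n = len(log.attempts)
    n_success = counts["success"]
    rate = math.floor(100.0 * n_success / n + 0.5)  # round half up
    return {
        "n_attempts": n,
        "n_success": n_success,
        "success_rate_percent": rate,
        "counts": counts,
    }
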
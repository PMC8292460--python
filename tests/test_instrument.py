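"""Plate geometry, calibration mapping, scan/transfer planning, G-code."""

import numpy as np
import pytest

import spheropick as sp
from spheropick.instrument import (Aspirate, Dispense, MoveStage, PipetteX,
                                   PipetteZ, TransferAttempt, validate_plan)
from spheropick.morphometrics import SpheroidRecord


def make_record(label, stage_um=(5000.0, 6000.0)):
    return SpheroidRecord(label=label, area_um2=25_000, perimeter_um=600,
                          circularity=0.87, equivalent_diameter_um=178.4,
                          solidity=0.98, volume_um3=2.9e6, centroid_px=(0, 0),
                          bbox_px=(0, 0, 1, 1), stage_um=stage_um)


CAL = sp.Calibration(tip_px=(256.0, 256.0), z_min_mm=2.0, um_per_px=2.0)
P96 = sp.PLATE_LAYOUTS["96well"]


class TestWellCenter:
    def test_a1_is_the_offset(self):
        assert sp.well_center(P96, "A1") == pytest.approx(P96.a1_offset_mm)

    def test_h12_slas_arithmetic(self):
        assert sp.well_center(P96, "H12") == pytest.approx((113.38, 74.24))

    @pytest.mark.parametrize("bad", ["Z9", "A13", "I1", "1A", ""])
    def test_out_of_range_wells_rejected(self, bad):
        with pytest.raises(ValueError):
            sp.well_center(P96, bad)

    def test_all_default_layouts_fit_their_footprint(self):
        for layout in sp.PLATE_LAYOUTS.values():
            last = layout.well_ids()[-1]
            x, y = sp.well_center(layout, last)
            assert x + layout.well_diameter_mm / 2 <= layout.footprint_mm[0]
            assert y + layout.well_diameter_mm / 2 <= layout.footprint_mm[1]


class TestImageToStage:
    def test_tip_pixel_is_fixed_point(self):
        assert sp.image_to_stage(CAL, (256.0, 256.0), (10.0, 20.0)) == (10.0, 20.0)

    def test_column_offset_maps_to_x(self):
        x, y = sp.image_to_stage(CAL, (256.0, 356.0), (0.0, 0.0))
        assert (x, y) == pytest.approx((0.2, 0.0))

    def test_axis_sign_flips_displacement(self):
        cal = sp.Calibration(tip_px=(256.0, 256.0), z_min_mm=2.0, um_per_px=2.0,
                             axis_sign=(-1, 1))
        x, _ = sp.image_to_stage(cal, (256.0, 356.0), (0.0, 0.0))
        assert x == pytest.approx(-0.2)

    def test_round_trip_within_half_pixel(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            px = tuple(rng.uniform(0, 512, 2))
            current = tuple(rng.uniform(0, 100, 2))
            target = sp.image_to_stage(CAL, px, current)
            back = sp.stage_to_image(CAL, target, current)
            assert abs(back[0] - px[0]) < 0.5 and abs(back[1] - px[1]) < 0.5

    def test_incomplete_calibration_rejected(self):
        with pytest.raises(ValueError):
            sp.Calibration(tip_px=None, z_min_mm=2.0, um_per_px=2.0)
        with pytest.raises(ValueError):
            sp.Calibration(tip_px=(0, 0), z_min_mm=2.0, um_per_px=0.0)


class TestPlanScan:
    LAYOUT = sp.PlateLayout("test", 1, 1, 9.0, (10.0, 10.0), 10.0, (30.0, 30.0))

    def test_exact_tiling(self):
        assert len(sp.plan_scan(self.LAYOUT, ["A1"], (5.0, 5.0), 0.0)) == 4

    def test_half_overlap_halves_step(self):
        assert len(sp.plan_scan(self.LAYOUT, ["A1"], (5.0, 5.0), 0.5)) == 9

    def test_small_well_single_centered_tile(self):
        tiles = sp.plan_scan(self.LAYOUT, ["A1"], (12.0, 12.0), 0.0)
        assert tiles == [(10.0, 10.0)]

    def test_every_well_point_covered(self):
        fov = (4.0, 4.0)
        tiles = sp.plan_scan(self.LAYOUT, ["A1"], fov, 0.3)
        cx, cy = 10.0, 10.0
        ext = self.LAYOUT.well_diameter_mm
        grid = np.linspace(-ext / 2, ext / 2, 21)
        for dx in grid:
            for dy in grid:
                px, py = cx + dx, cy + dy
                assert any(abs(px - tx) <= fov[0] / 2 + 1e-9 and
                           abs(py - ty) <= fov[1] / 2 + 1e-9 for tx, ty in tiles)

    def test_serpentine_rows_alternate_direction(self):
        tiles = sp.plan_scan(self.LAYOUT, ["A1"], (4.0, 4.0), 0.0)
        xs_by_row = {}
        for x, y in tiles:
            xs_by_row.setdefault(round(y, 6), []).append(x)
        rows = [xs_by_row[k] for k in sorted(xs_by_row)]
        assert rows[0] == sorted(rows[0])
        assert rows[1] == sorted(rows[1], reverse=True)

    def test_invalid_fov_rejected(self):
        with pytest.raises(ValueError):
            sp.plan_scan(self.LAYOUT, ["A1"], (0.0, 5.0), 0.0)


class TestPlanTransfer:
    def test_empty_selection_only_retracts(self):
        plan = sp.plan_transfer([], P96, [], CAL)
        assert len(plan.commands) == 1 and isinstance(plan.commands[0], PipetteX)

    def test_two_spheroids_interleaved_aspirate_dispense(self):
        plan = sp.plan_transfer([make_record(1), make_record(2)], P96,
                                ["A1", "A2"], CAL)
        kinds = [type(c).__name__ for c in plan.commands]
        assert kinds.count("Aspirate") == 2 and kinds.count("Dispense") == 2
        # each aspirate precedes its dispense
        validate_plan(plan)
        assert plan.metadata[0]["target_well"] == "A1"

    def test_volume_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            sp.plan_transfer([make_record(1)], P96, ["A1"], CAL, volume_ul=5.0)

    def test_missing_stage_coordinates_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            sp.plan_transfer([make_record(1, stage_um=None)], P96, ["A1"], CAL)

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError, match="wells"):
            sp.plan_transfer([make_record(1), make_record(2)], P96, ["A1"], CAL)

    def test_pipette_never_below_z_min(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(1, 6))
            recs = [make_record(i + 1, (float(rng.uniform(0, 9e4)),
                                        float(rng.uniform(0, 6e4)))) for i in range(n)]
            wells = P96.well_ids()[:n]
            plan = sp.plan_transfer(recs, P96, wells, CAL,
                                    volume_ul=float(rng.uniform(3, 4)))
            for cmd in plan.commands:
                if isinstance(cmd, PipetteZ):
                    assert cmd.mm >= CAL.z_min_mm


class TestEmitGcode:
    def test_empty_plan_is_header_and_footer_only(self):
        text = sp.emit_gcode(sp.TransferPlan(commands=[], metadata=[]))
        assert "G28" in text and text.strip().endswith("; end of transfer session")
        assert "G1 E" not in text

    def test_aspirate_maps_to_negative_extruder_move(self):
        plan = sp.TransferPlan(commands=[PipetteZ(2.0), Aspirate(3.0), Dispense(3.0)],
                               metadata=[{}], z_min_mm=2.0)
        text = sp.emit_gcode(plan, sp.MotionConfig(ul_to_mm=0.5))
        assert "G1 E-1.500" in text and "G1 E1.500" in text

    def test_deterministic(self):
        plan = sp.plan_transfer([make_record(1)], P96, ["B3"], CAL)
        cfg = sp.MotionConfig()
        assert sp.emit_gcode(plan, cfg) == sp.emit_gcode(plan, cfg)

    def test_stage_moves_are_comments(self):
        plan = sp.plan_transfer([make_record(1)], P96, ["A1"], CAL)
        text = sp.emit_gcode(plan)
        assert any(line.startswith(";STAGE MOVE") for line in text.splitlines())

    def test_volume_conservation(self):
        plan = sp.plan_transfer([make_record(i + 1) for i in range(3)], P96,
                                ["A1", "A2", "A3"], CAL)
        text = sp.emit_gcode(plan, sp.MotionConfig(ul_to_mm=0.4))
        intake = sum(float(l.split()[1][2:]) for l in text.splitlines()
                     if l.startswith("G1 E-"))
        expel = sum(float(l.split()[1][1:]) for l in text.splitlines()
                    if l.startswith("G1 E") and not l.startswith("G1 E-"))
        assert intake == pytest.approx(expel)

    def test_missing_conversion_rejected(self):
        plan = sp.TransferPlan(commands=[], metadata=[])
        with pytest.raises(ValueError, match="ul_to_mm"):
            sp.emit_gcode(plan, sp.MotionConfig(ul_to_mm=None))


class TestSuccessStats:
    @staticmethod
    def log_of(n_success, failures):
        attempts = [TransferAttempt(f"s{i}", "success") for i in range(n_success)]
        attempts += [TransferAttempt(f"f{i}", kind) for i, kind in enumerate(failures)]
        return sp.TransferLog(attempts)

    def test_semi_automatic_benchmark(self):
        # 28 attempts: 2 never picked up, 1 lost when expelling, 25 good
        log = self.log_of(25, ["pick_up_error", "pick_up_error", "expel_error"])
        stats = sp.success_stats(log)
        assert stats["n_attempts"] == 28
        assert stats["success_rate_percent"] == 89
        assert stats["counts"]["expel_error"] == 1

    def test_fully_automatic_benchmark(self):
        log = self.log_of(24, ["pick_up_error"] * 4 + ["expel_error", "double_pick"])
        stats = sp.success_stats(log)
        assert stats["n_attempts"] == 30
        assert stats["success_rate_percent"] == 80

    def test_all_successful(self):
        assert sp.success_stats(self.log_of(7, []))["success_rate_percent"] == 100

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            TransferAttempt("x", "vanished")

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            sp.success_stats(sp.TransferLog([]))

    def test_csv_round_trip(self, tmp_path):
        log = self.log_of(3, ["double_pick"])
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = sp.TransferLog.from_csv(path)
        assert sp.success_stats(back) == sp.success_stats(log)
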
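"""Critical-time scans, drag calibration, table replication, recommendations."""

from dataclasses import replace

import pandas as pd
import pytest

from canalith import (
    ExperimentConfig,
    OperatorNoiseSpec,
    calibrate_drag,
    find_critical_time,
    recommend,
    replicate_bench_table,
)
from canalith.errors import CalibrationError, InvalidParameterError
from canalith.protocol import LEVER_ARM_M


def make_config(canal, materials, maneuver, lam, d_um=250.0, alpha=20.0, v=90.0, **kw):
    return ExperimentConfig(
        canal=canal,
        materials=replace(materials, particle_diameter=d_um * 1e-6),
        drag_correction=lam,
        maneuver=replace(
            maneuver, extension_angle_deg=alpha, maneuver_velocity_deg_s=v
        ),
        **kw,
    )


class TestCalibration:
    def test_calibrated_drag_is_order_four(self, drag_lambda):
        """Free Stokes settles the bench particle in ~1.75 s per radian-scale
        arc; reproducing a 9 s critical time needs roughly 4x more drag."""
        assert 2.0 <= drag_lambda <= 8.0

    def test_calibration_cell_hits_target(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        cfg = make_config(
            canal, model_materials, maneuver_template, drag_lambda, alpha=30.0, v=90.0
        )
        res = find_critical_time(cfg, refine_to=0.05)
        assert res.critical_time_s == pytest.approx(9.0, abs=0.1)

    def test_free_stokes_undershoots_target(
        self, canal, model_materials, maneuver_template
    ):
        cfg = make_config(
            canal, model_materials, maneuver_template, 1.0, alpha=30.0, v=90.0
        )
        res = find_critical_time(cfg)
        assert res.critical_time_s is not None
        assert res.critical_time_s < 9.0

    def test_critical_time_monotone_in_drag(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        base = make_config(
            canal, model_materials, maneuver_template, drag_lambda, alpha=30.0, v=90.0
        )
        doubled = replace(base, drag_correction=2.0 * drag_lambda)
        t1 = find_critical_time(base).critical_time_s
        t2 = find_critical_time(doubled).critical_time_s
        assert t2 > t1

    def test_unbracketable_target_raises(
        self, canal, model_materials, maneuver_template
    ):
        with pytest.raises(CalibrationError):
            calibrate_drag(
                canal,
                model_materials,
                maneuver_template,
                bracket=(1.0, 1.2),
                target_critical_time=9.0,
            )


class TestCriticalTimeScan:
    def test_no_extension_yields_no_critical_time(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        cfg = make_config(
            canal, model_materials, maneuver_template, drag_lambda, alpha=0.0, v=135.0
        )
        res = find_critical_time(cfg, max_time=300.0)
        assert res.critical_time_s is None
        assert res.reported_s is None
        # the scan-bound probe proves failure everywhere below it
        assert (300.0, "failure") in res.history

    def test_outcome_monotone_in_resting_time(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        from canalith.protocol import _outcome

        cfg = make_config(canal, model_materials, maneuver_template, drag_lambda)
        res = find_critical_time(cfg)
        tc = res.critical_time_s
        assert _outcome(cfg, tc - 2.0) == "failure"
        assert _outcome(cfg, tc + 5.0) == "success"
        # scan history shows failures strictly before the first success
        scanned = [(t, o) for t, o in res.history if t == int(t)]
        first_success = min(t for t, o in scanned if o == "success")
        assert all(o == "failure" for t, o in scanned if t < first_success)

    def test_reported_time_is_first_scanned_success(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        cfg = make_config(canal, model_materials, maneuver_template, drag_lambda)
        res = find_critical_time(cfg)
        assert res.reported_s == float(int(res.critical_time_s) + 1)

    def test_undecided_outcome_raises_with_guidance(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        cfg = make_config(
            canal,
            model_materials,
            replace(maneuver_template, final_observation_s=0.05),
            drag_lambda,
        )
        with pytest.raises(RuntimeError, match="final_observation_s"):
            find_critical_time(cfg)


class TestStochasticScan:
    def test_noisy_scan_has_band_and_is_no_earlier_than_deterministic(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        lever = replace(
            maneuver_template, pivot_offset_m=LEVER_ARM_M, ramp_time_s=0.15
        )
        det = find_critical_time(
            make_config(canal, model_materials, lever, drag_lambda)
        )
        sto = find_critical_time(
            make_config(
                canal,
                model_materials,
                lever,
                drag_lambda,
                noise=OperatorNoiseSpec(seed=42),
            )
        )
        assert sto.critical_time_s is not None
        assert sto.inconclusive_onset_s is not None
        assert sto.inconclusive_onset_s <= sto.critical_time_s
        assert sto.critical_time_s >= det.critical_time_s

    def test_zero_noise_collapses_to_deterministic_grid_value(
        self, canal, model_materials, maneuver_template, drag_lambda
    ):
        lever = replace(
            maneuver_template, pivot_offset_m=LEVER_ARM_M, ramp_time_s=0.15
        )
        det = find_critical_time(
            make_config(canal, model_materials, lever, drag_lambda)
        )
        zero = OperatorNoiseSpec(
            stop_angle_sd_deg=0.0, velocity_fraction_sd=0.0, resting_time_sd_s=0.0
        )
        sto = find_critical_time(
            make_config(canal, model_materials, lever, drag_lambda, noise=zero)
        )
        assert sto.critical_time_s == det.reported_s


@pytest.fixture(scope="module")
def table(canal, model_materials, maneuver_template, drag_lambda):
    return replicate_bench_table(canal, model_materials, maneuver_template, drag_lambda)


class TestTableReplication:
    def test_critical_times_decrease_with_extension_angle(self, table):
        stepper = table[(table.setup == "stepper") & (table.particle_diameter_um == 250)]
        for v in (90, 135, 180):
            col = stepper[stepper.maneuver_velocity_deg_s == v]
            times = col.sort_values("extension_angle_deg")["critical_time_s"]
            vals = [t for t in times if pd.notna(t)]
            assert vals == sorted(vals, reverse=True)
            # no extension -> impossible
            assert pd.isna(times.iloc[0])

    def test_critical_times_decrease_with_velocity(self, table):
        for (_, d, a), grp in table[table.critical_time_s.notna()].groupby(
            ["setup", "particle_diameter_um", "extension_angle_deg"]
        ):
            times = grp.sort_values("maneuver_velocity_deg_s")["critical_time_s"].tolist()
            assert times == sorted(times, reverse=True)

    def test_small_particle_times_about_twice_large(self, table):
        for v in (90, 135, 180):
            sel = table[
                (table.setup == "stepper")
                & (table.extension_angle_deg == 20)
                & (table.maneuver_velocity_deg_s == v)
            ]
            small = sel[sel.particle_diameter_um == 180].critical_time_s.iloc[0]
            large = sel[sel.particle_diameter_um == 250].critical_time_s.iloc[0]
            assert small / large == pytest.approx(2.0, rel=0.15)

    def test_lever_no_slower_than_stepper_within_two_seconds(self, table):
        for v in (90, 135, 180):
            sel = table[
                (table.particle_diameter_um == 250)
                & (table.extension_angle_deg == 20)
                & (table.maneuver_velocity_deg_s == v)
            ]
            stepper = sel[sel.setup == "stepper"].critical_time_s.iloc[0]
            lever = sel[sel.setup == "lever"].critical_time_s.iloc[0]
            assert lever <= stepper
            assert stepper - lever <= 2.0

    def test_calibration_cell_flagged(self, table):
        flagged = table[table.is_calibration_cell]
        assert len(flagged) == 1
        row = flagged.iloc[0]
        assert (row.particle_diameter_um, row.extension_angle_deg) == (250, 30)

    def test_leave_one_out_preserves_ordering_within_particle_size(
        self, canal, model_materials, maneuver_template, table
    ):
        """Calibrating on a different cell must not change the predicted
        ordering of the 250 um stepper cells (the bench ordering)."""
        lam2 = calibrate_drag(
            canal,
            model_materials,
            maneuver_template,
            calibration_cell=(250e-6, 20.0, 135.0),
            target_critical_time=13.0,
        )
        cells = [("stepper", 250, a, v) for a in (10, 20, 30) for v in (90, 135, 180)]
        refit = replicate_bench_table(
            canal, model_materials, maneuver_template, lam2, cells=cells
        )
        base = table[(table.setup == "stepper") & (table.particle_diameter_um == 250)]
        base = base[base.extension_angle_deg > 0].sort_values(
            ["extension_angle_deg", "maneuver_velocity_deg_s"]
        )
        other = refit.sort_values(["extension_angle_deg", "maneuver_velocity_deg_s"])
        rank_a = base["critical_time_s"].rank().tolist()
        rank_b = other["critical_time_s"].rank().tolist()
        assert rank_a == rank_b


class TestRecommendation:
    @pytest.fixture()
    def reference(self):
        return pd.DataFrame(
            [
                {"setup": "lever", "particle_diameter_um": 250,
                 "extension_angle_deg": 20.0, "maneuver_velocity_deg_s": 135.0,
                 "critical_time_s": 11.0},
                {"setup": "stepper", "particle_diameter_um": 250,
                 "extension_angle_deg": 20.0, "maneuver_velocity_deg_s": 90.0,
                 "critical_time_s": 16.0},
            ]
        )

    def test_quarter_cross_section_quadruples_resting_time(self, reference):
        rec = recommend(25.0, reference)
        assert rec.cross_section_multiplier == pytest.approx(4.0)
        assert rec.resting_time_raw_s == pytest.approx(44.0)
        assert rec.resting_time_s == 45.0  # rounded up to the next 5 s
        assert rec.resting_time_low_velocity_raw_s == pytest.approx(64.0)

    def test_recommended_angles_and_velocity(self, reference):
        rec = recommend(25.0, reference)
        assert rec.first_movement_deg == 110.0
        assert rec.second_movement_deg == 220.0
        assert rec.velocity_deg_s == 135.0

    def test_small_target_warns_large_target_rejected(self, reference):
        with pytest.warns(UserWarning):
            recommend(10.0, reference)
        with pytest.raises(InvalidParameterError):
            recommend(60.0, reference)
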
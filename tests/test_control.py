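import numpy as np
import pytest

from optoloop.control import (AvoidanceConfig, GainSchedule,
                              MigrationControllerConfig, PIDController,
                              PIDGains, apply_avoidance, detect_collision,
                              direction_sign, migration_controller_step,
                              schedule_gains, select_aoi)
from optoloop.geometry import circle_path
from optoloop.plants import LexyPlant, lexy_step
from optoloop.tuning import normalised_cytosol_range


def disc_mask(shape, center_rc, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius ** 2


class TestSelectAoi:
    def test_half_disc_faces_target(self):
        mask = disc_mask((64, 64), (32, 32), 10)
        aoi = select_aoi(mask, (32.0, 32.0), (60.0, 32.0), 0.5)
        assert aoi.sum() == pytest.approx(mask.sum() / 2, rel=0.1)
        rr, cc = np.nonzero(aoi)
        # AOI centroid lies on the centroid->target ray (+x)
        assert cc.mean() > 32.0
        assert rr.mean() == pytest.approx(32.0, abs=0.5)

    def test_full_fraction_whole_mask(self):
        mask = disc_mask((32, 32), (16, 16), 6)
        aoi = select_aoi(mask, (16.0, 16.0), (30.0, 16.0), 1.0)
        assert np.array_equal(aoi, mask)

    def test_matches_per_pixel_quantile_oracle(self):
        rng = np.random.default_rng(2)
        mask = rng.random((40, 40)) > 0.6       # asymmetric mask
        centroid, target = (20.0, 20.0), (35.0, 8.0)
        frac = 0.3
        aoi = select_aoi(mask, centroid, target, frac)
        u = np.array([35.0 - 20.0, 8.0 - 20.0])
        u = u / np.linalg.norm(u)
        rows, cols = np.nonzero(mask)
        proj = (cols - centroid[0]) * u[0] + (rows - centroid[1]) * u[1]
        thr = np.quantile(proj, 1 - frac)
        expect = np.zeros_like(mask)
        expect[rows[proj >= thr], cols[proj >= thr]] = True
        assert np.array_equal(aoi, expect)

    def test_degenerate_direction_reuses_previous(self):
        mask = disc_mask((32, 32), (16, 16), 6)
        prev = np.zeros_like(mask)
        prev[10:12, 10:12] = True
        events = []
        aoi = select_aoi(mask, (16.0, 16.0), (16.0, 16.0), 0.5,
                         previous=prev, events=events)
        assert np.array_equal(aoi, prev)
        assert events


class TestMigrationController:
    def test_on_path_aoi_faces_forward(self):
        path = circle_path((64.0, 64.0), 40.0)
        centroid = np.array([104.0, 64.0])       # on the circle, angle 0
        mask = disc_mask((128, 128), (64, 104), 10)
        cfg = MigrationControllerConfig()
        cmd, proj, _ = migration_controller_step(centroid, mask, path, cfg)
        assert proj.deviation < 0.01
        rr, cc = np.nonzero(cmd.masks[0])
        # tangent at angle 0 points toward +y: AOI below the centroid row
        assert rr.mean() > 64.0

    def test_inside_circle_aoi_has_outward_component(self):
        path = circle_path((64.0, 64.0), 40.0)
        centroid = np.array([99.0, 64.0])        # 5 µm inside the circle
        mask = disc_mask((128, 128), (64, 99), 10)
        cmd, proj, _ = migration_controller_step(
            centroid, mask, path, MigrationControllerConfig())
        rr, cc = np.nonzero(cmd.masks[0])
        aoi_dir = np.array([cc.mean() - 99.0, rr.mean() - 64.0])
        radial = np.array([1.0, 0.0])            # outward at this position
        assert aoi_dir @ radial > 0

    def test_lost_cell_light_off(self):
        path = circle_path((64.0, 64.0), 40.0)
        cmd, proj, _ = migration_controller_step(
            np.array([0.0, 0.0]), None, path, MigrationControllerConfig())
        assert cmd.masks == []
        assert proj is None


class TestAvoidance:
    def test_head_on_flagging_algebra(self):
        cfg = AvoidanceConfig(lookahead_horizon=5, collision_distance=10.0)
        # gap 30, closing 3 µm/frame -> 30 - 15 = 15 >= 10: not flagged
        pos = {1: (0.0, 0.0), 2: (30.0, 0.0)}
        vel = {1: (1.5, 0.0), 2: (-1.5, 0.0)}
        assert detect_collision(pos, vel, cfg) == set()
        # closing 5 µm/frame -> 30 - 25 = 5 < 10: flagged
        vel = {1: (2.5, 0.0), 2: (-2.5, 0.0)}
        assert detect_collision(pos, vel, cfg) == {(1, 2)}

    def test_parallel_tracks_not_flagged(self):
        cfg = AvoidanceConfig(collision_distance=10.0)
        pos = {1: (0.0, 0.0), 2: (0.0, 50.0)}
        vel = {1: (2.0, 0.0), 2: (2.0, 0.0)}
        assert detect_collision(pos, vel, cfg) == set()

    def test_one_cell_yields_and_flips_rear(self):
        from optoloop.microscope import IlluminationCommand
        mask1 = disc_mask((64, 64), (32, 20), 8)
        mask2 = disc_mask((64, 64), (32, 44), 8)
        fwd1 = select_aoi(mask1, (20.0, 32.0), (44.0, 32.0), 0.5)
        fwd2 = select_aoi(mask2, (44.0, 32.0), (20.0, 32.0), 0.5)
        cmds = {1: IlluminationCommand([fwd1], [0.23]),
                2: IlluminationCommand([fwd2], [0.23])}
        pos = {1: np.array([20.0, 32.0]), 2: np.array([44.0, 32.0])}
        vel = {1: np.array([2.0, 0.0]), 2: np.array([-2.0, 0.0])}
        out = apply_avoidance(cmds, {(1, 2)}, pos, vel,
                              {1: mask1, 2: mask2})
        # lower id yields: AOI centroid projection on motion dir negative
        rr, cc = np.nonzero(out[1].masks[0])
        assert (cc.mean() - 20.0) * 2.0 < 0
        # the other cell unchanged
        assert np.array_equal(out[2].masks[0], fwd2)

    def test_no_collisions_identity(self):
        cmds = {1: "sentinel"}
        assert apply_avoidance(cmds, set(), {}, {}, {}) == cmds


class TestPID:
    def test_zero_error_zero_output(self):
        pid = PIDController(PIDGains(50.0, 0.1, 0.0))
        assert pid.step(0.5, 0.5, 15.0) == 0.0

    def test_proportional_law(self):
        pid = PIDController(PIDGains(50.0, 0.0, 0.0), i_max=100.0)
        for _ in range(5):
            u = pid.step(0.6, 0.5, 15.0)
            assert u == pytest.approx(5.0)

    def test_output_clamped(self):
        pid = PIDController(PIDGains(1000.0, 0.0, 0.0), i_max=10.4)
        assert pid.step(1.0, 0.0, 15.0) == 10.4
        assert pid.step(0.0, 1.0, 15.0) == 0.0

    def test_nonfinite_error_holds_output(self):
        pid = PIDController(PIDGains(10.0, 0.0, 0.0))
        u0 = pid.step(0.6, 0.4, 15.0)
        u1 = pid.step(0.6, np.nan, 15.0)
        assert u1 == u0
        assert pid.state.fault

    def test_integral_removes_steady_state_error(self, lexy_plant):
        """Closed loop on the transport plant: PI drives the error to zero."""
        lo, hi = normalised_cytosol_range(lexy_plant, 10.4)
        pid = PIDController(PIDGains(2.0, 0.02, 0.0), i_max=10.4)
        p = lexy_plant
        m = 0.0
        for _ in range(400):
            u = pid.step(0.5, m, 15.0)
            p = lexy_step(p, u, 15.0)
            m = (p.C - lo) / (hi - lo)
        assert abs(0.5 - m) < 0.01

    def test_antiwindup_reduces_overshoot(self, lexy_plant):
        """Freezing the integral while saturated gives less overshoot than
        the same controller without it after a long infeasible epoch."""
        from optoloop.tuning import normalised_cytosol_range

        def run(antiwindup):
            lo, hi = normalised_cytosol_range(lexy_plant, 10.4)
            pid = PIDController(PIDGains(1.0, 0.05, 0.0), i_max=10.4,
                                antiwindup=antiwindup)
            p = lexy_plant
            m, peak = 0.0, 0.0
            for k in range(300):
                sp = 1.5 if k < 100 else 0.5     # unreachable, then feasible
                u = pid.step(sp, m, 15.0)
                p = lexy_step(p, u, 15.0)
                m = (p.C - lo) / (hi - lo)
                if k >= 100:
                    peak = max(peak, m - 0.5)
            return peak

        assert run(True) < run(False)


class TestGainSchedule:
    SCHED = GainSchedule([0.1, 0.5, 0.9],
                         [PIDGains(1.0, 0.01, 0.0),
                          PIDGains(3.0, 0.03, 0.0),
                          PIDGains(9.0, 0.09, 0.0)])

    def test_exact_operating_point(self):
        g = schedule_gains(0.5, self.SCHED)
        assert (g.kp, g.ki) == (3.0, 0.03)

    def test_midpoint_mean(self):
        g = schedule_gains(0.3, self.SCHED)
        assert g.kp == pytest.approx(2.0)
        assert g.ki == pytest.approx(0.02)

    def test_clamped_extrapolation(self):
        assert schedule_gains(0.0, self.SCHED).kp == 1.0
        assert schedule_gains(1.0, self.SCHED).kp == 9.0

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            GainSchedule([0.5, 0.1], [PIDGains(1.0), PIDGains(1.0)])

    def test_config_roundtrip(self):
        again = GainSchedule.from_config(self.SCHED.to_config())
        assert again.operating_points == self.SCHED.operating_points
        assert again.gains == self.SCHED.gains


class TestDirectionConvention:
    def test_signs(self):
        assert direction_sign("cytosol") == 1.0
        assert direction_sign("nucleus") == -1.0

    def test_nucleus_above_setpoint_drives_light(self):
        pid = PIDController(PIDGains(10.0, 0.0, 0.0))
        u = pid.step(0.5, 0.8, 15.0, sign=direction_sign("nucleus"))
        assert u > 0

    def test_cytosol_above_setpoint_no_drive(self):
        pid = PIDController(PIDGains(10.0, 0.0, 0.0))
        u = pid.step(0.5, 0.8, 15.0, sign=direction_sign("cytosol"))
        assert u == 0.0


def test_trajectory_loop_contracts_noise_free():
    """A cell displaced off a straight path converges back monotonically
    (after the turning transient) under the orientation-correction loop."""
    from optoloop.geometry import GuidePath, project_to_path
    from optoloop.plants import MigratingCell, migrate_step

    path = GuidePath(np.array([[0.0, 0.0], [4000.0, 0.0]]))
    cell = MigratingCell(position=np.array([0.0, 15.0]), polarity=(1.0, 0.0))
    cfg = MigrationControllerConfig(irradiance=2.0)
    devs = []
    for _ in range(120):
        proj = project_to_path(cell.position, path)
        devs.append(proj.deviation)
        from optoloop.geometry import next_setpoint
        target, _ = next_setpoint(proj, path, cfg.lookahead)
        cell = migrate_step(cell, cfg.irradiance,
                            np.asarray(target) - cell.position, 60.0, rng=None)
    devs = np.array(devs)
    tail = devs[10:]
    # monotone decrease until the path is reached (within 10 nm), then stays
    reached = np.flatnonzero(tail < 0.01)
    assert reached.size
    assert np.all(np.diff(tail[: reached[0] + 1]) <= 1e-9)
    assert np.all(tail[reached[0]:] < 0.01)
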
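"""Model-informed PID tuning.

The transport plant is strongly nonlinear in the operating point: the static
gain dC*/dI is largest near the dark state and collapses as the activated
exporter fraction saturates.  A single gain set tuned at one point is
therefore either sluggish or overshooting elsewhere — the reason the
titration controller is gain-scheduled.  The tuner runs an
overshoot-constrained grid search per operating point on the simulated plant
(classical step-response rules assume a fixed plant gain, which this plant
does not have) and returns the value–gain matrix.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .control import GainSchedule, PIDController, PIDGains
from .plants import LexyPlant, lexy_step, lexy_steady_state

__all__ = ["normalised_cytosol_range", "tune_pid", "TuningError"]

DEFAULT_OPERATING_POINTS = (0.1, 0.3, 0.5, 0.7, 0.9)


class TuningError(RuntimeError):
    """Raised when no gain set satisfies the design constraints."""


def normalised_cytosol_range(plant: LexyPlant, i_max: float) -> tuple[float, float]:
    """(dark, saturating-light) cytosolic concentrations — the dynamic range."""
    _, _, c_dark = lexy_steady_state(plant, 0.0)
    _, _, c_light = lexy_steady_state(plant, i_max)
    return c_dark, c_light


def _holding_irradiance(plant: LexyPlant, c: float) -> float:
    """Constant irradiance whose steady state holds cytosolic level ``c``."""
    T = plant.total
    if c <= 0 or c >= T:
        return 0.0 if c <= 0 else np.inf
    keA = plant.k_imp * c / (T - c)
    A = min(keA / plant.k_exp, 1.0 - 1e-9)
    return plant.k_off * A / (plant.k_on_per_I * (1.0 - A))


def _closed_loop_response(plant: LexyPlant, gains: PIDGains, setpoint: float,
                          start: float, i_max: float, dt: float,
                          n_steps: int, noise_sigma: float = 0.0,
                          noise_seed: int = 12345) -> np.ndarray:
    """Plant-level closed loop; returns the measured normalised cytosol trace.

    The plant starts at the steady state of the starting level and the PID
    integral is pre-loaded with the irradiance holding it there (bumpless
    start), as the carried-over integral of a staircase epoch would be.
    ``noise_sigma`` adds seeded Gaussian measurement noise (normalised
    units); the same realisation is replayed for every candidate so the
    comparison stays fair.
    """
    lo, hi = normalised_cytosol_range(plant, i_max)
    span = hi - lo
    c0 = lo + start * span
    u0 = _holding_irradiance(plant, c0)
    T = plant.total
    A0 = (min(plant.k_imp * c0 / ((T - c0) * plant.k_exp), 1.0)
          if T > c0 else 1.0)
    p = replace(plant, C=c0, N=(T - c0) / plant.vol_ratio, A=A0)
    pid = PIDController(gains, i_max=i_max)
    if gains.ki > 0:
        pid.state.integral = min(u0, i_max) / gains.ki
    rng = np.random.default_rng(noise_seed) if noise_sigma > 0 else None
    y = np.empty(n_steps)
    for k in range(n_steps):
        m = (p.C - lo) / span
        if rng is not None:
            m = float(np.clip(m + noise_sigma * rng.normal(), 0.0, 1.0))
        y[k] = m
        u = pid.step(setpoint, m, dt)
        p = lexy_step(p, u, dt)
    return y


def _evaluate(y: np.ndarray, setpoint: float, start: float,
              settle_band: float = 0.02) -> tuple[bool, float, float]:
    """(settled, mean_abs_error, overshoot) of one step response.

    The quality score is the mean absolute tracking error over the whole
    response, which penalises both a slow transition and the slow creep a
    weak integral term leaves behind.  Overshoot is expressed in normalised
    dynamic-range units (the units the steady-state error criterion uses),
    not as a fraction of the step.
    """
    step = setpoint - start
    if step == 0:
        return True, 0.0, 0.0
    # settling and overshoot on a 3-frame moving average so single noise
    # spikes neither disqualify a candidate nor fake a settling
    ys = np.convolve(np.pad(y, 1, mode="edge"), np.ones(3) / 3, "valid")
    overshoot = float(np.max((ys - setpoint) * np.sign(step)))
    inside = np.abs(ys - setpoint) <= settle_band
    settled = any(inside[i:].all() for i in range(len(ys)))
    return settled, float(np.mean(np.abs(y - setpoint))), max(overshoot, 0.0)


def _scheduled_response(plant: LexyPlant, schedule: GainSchedule,
                        levels, i_max: float, dt: float,
                        steps_per_epoch: int, noise_sigma: float = 0.0,
                        noise_seed: int = 12345) -> tuple[np.ndarray, np.ndarray]:
    """Gain-scheduled closed loop through a staircase of levels.

    Returns (trace, setpoint trace).  The scheduling variable is a 3-frame
    moving average of the measurement, as in the full loop; the run starts
    bumplessly at the first level's steady state.
    """
    from .control import SchedulingVariable, schedule_gains
    lo, hi = normalised_cytosol_range(plant, i_max)
    span = hi - lo
    c0 = lo + levels[0] * span
    u0 = _holding_irradiance(plant, c0)
    T = plant.total
    A0 = (min(plant.k_imp * c0 / ((T - c0) * plant.k_exp), 1.0)
          if T > c0 else 1.0)
    p = replace(plant, C=c0, N=(T - c0) / plant.vol_ratio, A=A0)
    g0 = schedule_gains(levels[0], schedule)
    pid = PIDController(g0, i_max=i_max)
    if g0.ki > 0:
        pid.state.integral = min(u0, i_max) / g0.ki
    sv = SchedulingVariable()
    rng = np.random.default_rng(noise_seed) if noise_sigma > 0 else None
    n = steps_per_epoch * (len(levels) - 1)
    y = np.empty(n)
    sp = np.empty(n)
    for k in range(n):
        target = levels[1 + k // steps_per_epoch]
        m = (p.C - lo) / span
        if rng is not None:
            m = float(np.clip(m + noise_sigma * rng.normal(), 0.0, 1.0))
        y[k] = m
        sp[k] = target
        gains = schedule_gains(sv.update(m), schedule)
        u = pid.step(target, m, dt, gains=gains)
        p = lexy_step(p, u, dt)
    return y, sp


def _fine_tune(schedule: GainSchedule, ensemble, i_max, dt, overshoot_max,
               noise_sigma, kp_grid, ki_grid,
               steps_per_epoch: int = 30) -> GainSchedule:
    """Coordinate-descent refinement of the value–gain matrix as deployed.

    Each operating point's gains are re-selected by simulating the scheduled
    controller (interpolation and all) through the mini-staircases passing
    that point, so cross-talk between neighbouring points is priced in.
    Points are refined top-down because high-point gains leak into lower
    holds through interpolation.
    """
    ops = list(schedule.operating_points)
    gains = list(schedule.gains)
    for j in reversed(range(len(ops))):
        below = ops[j - 1] if j > 0 else max(ops[j] - 0.2, 0.0)
        above = ops[j + 1] if j + 1 < len(ops) else min(ops[j] + 0.05, 0.95)
        sequences = [(below, ops[j], above), (above, ops[j], below)]
        best = None
        for kp in kp_grid:
            for ki in ki_grid:
                cand = list(gains)
                cand[j] = PIDGains(float(kp), float(ki), 0.0)
                sched = GainSchedule(ops, cand)
                worst = 0.0
                feasible = True
                for p in ensemble:
                    for seq in sequences:
                        y, sp = _scheduled_response(
                            p, sched, seq, i_max, dt, steps_per_epoch,
                            noise_sigma)
                        for e in range(len(seq) - 1):
                            seg = slice(e * steps_per_epoch,
                                        (e + 1) * steps_per_epoch)
                            settled, score, ovs = _evaluate(
                                y[seg], seq[e + 1], seq[e])
                            if not settled or ovs > overshoot_max:
                                feasible = False
                                break
                            worst = max(worst, score)
                        if not feasible:
                            break
                    if not feasible:
                        break
                if feasible and (best is None or worst < best[0]):
                    best = (worst, cand[j])
        if best is not None:
            gains[j] = best[1]
    return GainSchedule(ops, gains)


def tune_pid(plant: LexyPlant, operating_points=DEFAULT_OPERATING_POINTS,
             i_max: float = 10.4, dt: float = 15.0, n_steps: int = 80,
             overshoot_max: float = 0.05, kp_grid=None, ki_grid=None,
             ensemble_expressions=(0.6, 1.0, 1.6),
             noise_sigma: float = 0.005, fine_tune: bool = True) -> GainSchedule:
    """Grid-search PID gains per operating point on the simulated plant.

    For each operating point, candidate gains are evaluated on step responses
    toward the point from below and from above, across an ensemble of
    expression levels (the dominant axis of cell-to-cell variation, since the
    export rate falls with expression), with seeded measurement noise of
    ``noise_sigma`` normalised units in the loop so noise-amplifying gains
    score what they cost.  A candidate is feasible when every
    ensemble response settles with overshoot within the bound (default 5%);
    the feasible candidate with the smallest worst-case mean absolute
    tracking error wins.  Raises :class:`TuningError` when the plant has no
    light sensitivity or no candidate is feasible.
    """
    lo, hi = normalised_cytosol_range(plant, i_max)
    if hi - lo <= 1e-9 * max(1.0, plant.total):
        raise TuningError("plant has zero light sensitivity: "
                          "saturating light does not move the cytosolic level")
    ops = list(operating_points)
    if kp_grid is None:
        kp_grid = np.geomspace(0.05, 100.0, 12)
    if ki_grid is None:
        ki_grid = np.geomspace(0.001, 0.5, 12)
    ensemble = [replace(plant, expression=plant.expression * e)
                for e in ensemble_expressions]
    gains_out = []
    for op in ops:
        starts = [s for s in (max(op - 0.2, 0.0), min(op + 0.2, 0.95))
                  if abs(s - op) > 1e-9]
        best = None
        for kp in kp_grid:
            for ki in ki_grid:
                g = PIDGains(float(kp), float(ki), 0.0)
                worst = 0.0
                feasible = True
                for p in ensemble:
                    for start in starts:
                        y = _closed_loop_response(p, g, op, start, i_max,
                                                  dt, n_steps, noise_sigma)
                        settled, score, ovs = _evaluate(y, op, start)
                        if not settled or ovs > overshoot_max:
                            feasible = False
                            break
                        worst = max(worst, score)
                    if not feasible:
                        break
                if feasible and (best is None or worst < best[0]):
                    best = (worst, g)
        if best is None:
            raise TuningError(
                f"no gain pair settles at operating point {op} with "
                f"overshoot <= {overshoot_max:.0%}")
        gains_out.append(best[1])
    schedule = GainSchedule(ops, gains_out)
    if fine_tune:
        schedule = _fine_tune(schedule, ensemble, i_max, dt, overshoot_max,
                              noise_sigma, kp_grid, ki_grid)
    return schedule
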
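"""Feedback controllers.

* Trajectory tracking for cell migration: project the tracked centroid onto
  the guide path, pick the next setpoint a fixed arc lookahead further on,
  and illuminate the front sector of the cell mask facing it (the direct
  orientation-correction law).
* Multi-cell collision avoidance: constant-velocity lookahead; on an imminent
  collision the yielding cell's illumination flips to its rear sector,
  pulling it back against its motion.
* PID with derivative-on-measurement, output clamping to [0, I_max] and
  conditional-integration anti-windup, plus a gain-scheduled variant whose
  gains interpolate over operating points of the measured intensity (the
  value–gain matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GuidePath, project_to_path, next_setpoint
from .microscope import IlluminationCommand

__all__ = [
    "select_aoi",
    "migration_controller_step",
    "detect_collision",
    "apply_avoidance",
    "PIDGains",
    "PIDState",
    "PIDController",
    "GainSchedule",
    "schedule_gains",
    "direction_sign",
    "AvoidanceConfig",
]


# ---------------------------------------------------------------------------
# AOI selection and migration control
# ---------------------------------------------------------------------------

def select_aoi(cell_mask: np.ndarray, centroid, target, front_fraction: float,
               pixel_size: float = 1.0,
               previous: np.ndarray | None = None,
               events: list | None = None) -> np.ndarray:
    """Front sector of the cell mask facing the target.

    Returns the subset of cell-mask pixels whose scalar projection onto the
    unit vector centroid→target lies in the top ``front_fraction`` quantile.
    A degenerate direction (target == centroid) reuses the previous AOI.
    """
    if not 0.0 < front_fraction <= 1.0:
        raise ValueError("front_fraction must lie in (0, 1]")
    mask = np.asarray(cell_mask, bool)
    if not mask.any():
        raise ValueError("cell mask is empty")
    direction = np.asarray(target, float) - np.asarray(centroid, float)
    norm = np.hypot(*direction)
    if norm == 0:
        if events is not None:
            events.append("degenerate AOI direction; previous AOI reused")
        if previous is not None:
            return previous
        raise ValueError("degenerate direction and no previous AOI")
    u = direction / norm
    rows, cols = np.nonzero(mask)
    # stage µm: x along columns, y along rows
    proj = (cols * pixel_size - centroid[0]) * u[0] + \
           (rows * pixel_size - centroid[1]) * u[1]
    if front_fraction >= 1.0:
        return mask.copy()
    thr = np.quantile(proj, 1.0 - front_fraction)
    keep = proj >= thr
    if not keep.any():            # guard against mass at the quantile
        keep = proj >= proj.max()
    aoi = np.zeros_like(mask)
    aoi[rows[keep], cols[keep]] = True
    return aoi


@dataclass
class MigrationControllerConfig:
    lookahead: float = 6.0           # µm of arc ahead of the projection
    front_fraction: float = 0.5
    irradiance: float = 0.23         # µW/cm² (constant-irradiance policy)
    frame_interval: float = 60.0     # s


def migration_controller_step(centroid, cell_mask, path: GuidePath,
                              config: MigrationControllerConfig,
                              pixel_size: float = 1.0,
                              previous_aoi: np.ndarray | None = None,
                              events: list | None = None):
    """One step of the orientation-correction trajectory controller.

    Composition: project the centroid to the path, select the setpoint
    ``lookahead`` µm further along, and illuminate the front sector of the
    cell facing it at the configured irradiance.  Returns
    ``(command, projection, done)``; a lost cell (``cell_mask`` None or
    empty) yields the light-off command.
    """
    if cell_mask is None or not np.asarray(cell_mask, bool).any():
        if events is not None:
            events.append("track lost; light off")
        return IlluminationCommand.dark(config.frame_interval), None, False
    proj = project_to_path(centroid, path)
    target, done = next_setpoint(proj, path, config.lookahead)
    aoi = select_aoi(cell_mask, centroid, target, config.front_fraction,
                     pixel_size, previous_aoi, events)
    cmd = IlluminationCommand(masks=[aoi], irradiances=[config.irradiance],
                              frame_interval=config.frame_interval)
    return cmd, proj, done


# ---------------------------------------------------------------------------
# collision avoidance
# ---------------------------------------------------------------------------

@dataclass
class AvoidanceConfig:
    lookahead_horizon: int = 5       # frames
    collision_distance: float = 30.0  # µm (centroid separation)

    def __post_init__(self):
        if self.lookahead_horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.collision_distance <= 0:
            raise ValueError("collision_distance must be positive")


def detect_collision(positions: dict, velocities: dict,
                     config: AvoidanceConfig) -> set:
    """Pairs whose constant-velocity extrapolations come within range.

    ``positions``/``velocities`` map track id to µm and µm/frame.  A pair is
    flagged iff at some integer step within the horizon (including now) the
    predicted separation drops below ``collision_distance``.
    """
    ids = sorted(positions)
    flagged = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pa, pb = np.asarray(positions[a], float), np.asarray(positions[b], float)
            va, vb = np.asarray(velocities[a], float), np.asarray(velocities[b], float)
            for k in range(config.lookahead_horizon + 1):
                gap = np.linalg.norm((pa + k * va) - (pb + k * vb))
                if gap < config.collision_distance:
                    flagged.add((a, b))
                    break
    return flagged


def apply_avoidance(commands: dict, flagged: set, positions: dict,
                    velocities: dict, cell_masks: dict,
                    front_fraction: float = 0.5, pixel_size: float = 1.0,
                    tie_break=None, events: list | None = None,
                    forced=()) -> dict:
    """Flip the yielding cell of each flagged pair to rear illumination.

    The yielding cell's AOI is re-selected toward centroid − velocity (the
    direction opposing its motion), pulling it back.  ``tie_break(a, b)``
    returns the yielding id; the default yields the lower track id.
    ``forced`` maps ids to retreat directions captured at flag time; they are
    pulled back regardless of the flags — the runner uses this for pullback
    hysteresis, keeping a yielder retreating (in its original rearward
    direction) until the pair has genuinely separated instead of letting it
    oscillate back.
    """
    if not flagged and not forced:
        return commands
    if tie_break is None:
        tie_break = min
    out = dict(commands)

    def _pull_back(y, rear_dir, note):
        if rear_dir is None:
            v = np.asarray(velocities[y], float)
            if np.linalg.norm(v) == 0:
                v = np.array([1.0, 0.0])
            rear_dir = -v / np.linalg.norm(v)
        centroid = np.asarray(positions[y], float)
        rear_target = centroid + np.asarray(rear_dir, float) * 10.0
        mask = cell_masks.get(y)
        if mask is None or not mask.any():
            return
        aoi = select_aoi(mask, centroid, rear_target, front_fraction,
                         pixel_size)
        out[y] = replace(out[y], masks=[aoi])
        if events is not None:
            events.append(f"avoidance: track {y} pulled back ({note})")

    done = set()
    forced = dict(forced)
    for a, b in sorted(flagged):
        y = tie_break(a, b)
        if y not in done:
            _pull_back(y, forced.get(y), f"pair {a},{b}")
            done.add(y)
    for y, rear_dir in forced.items():
        if y not in done and y in positions:
            _pull_back(y, rear_dir, "held")
            done.add(y)
    return out


# ---------------------------------------------------------------------------
# PID
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PIDGains:
    """PID gains in output units (µW/cm²) per unit normalised-intensity error."""

    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0

    def __post_init__(self):
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("gains must be >= 0")
        if self.kp == self.ki == self.kd == 0:
            raise ValueError("at least one gain must be positive")


@dataclass
class PIDState:
    integral: float = 0.0
    prev_measurement: float | None = None
    prev_output: float = 0.0
    last_ki: float | None = None
    fault: bool = False


def direction_sign(mode: str) -> float:
    """Error sign convention folding the plant gain to positive.

    Cytosol control: light raises cytosolic intensity, error =
    setpoint − measurement (+1).  Nucleus control: light lowers nuclear
    intensity, so the sign flips (−1) and nucleus-above-setpoint drives
    light on.
    """
    if mode == "cytosol":
        return 1.0
    if mode == "nucleus":
        return -1.0
    raise ValueError(f"unknown control mode {mode!r}")


class PIDController:
    """Clamped PID with derivative-on-measurement and anti-windup.

    The derivative acts on the measurement (not the error) so setpoint steps
    do not kick the output.  The integral is frozen whenever the unclamped
    output is saturated and integrating would push it further into
    saturation (conditional integration).
    """

    def __init__(self, gains: PIDGains, i_max: float = 10.4,
                 antiwindup: bool = True):
        if i_max <= 0:
            raise ValueError("i_max must be positive")
        self.gains = gains
        self.i_max = i_max
        self.antiwindup = antiwindup
        self.state = PIDState()

    def reset(self):
        self.state = PIDState()

    def step(self, setpoint: float, measurement: float, dt: float,
             sign: float = 1.0, gains: PIDGains | None = None) -> float:
        """One control interval; returns the commanded irradiance in [0, i_max]."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        g = gains if gains is not None else self.gains
        st = self.state
        # keep the integral's output contribution continuous across
        # scheduled gain changes
        if st.last_ki and g.ki > 0 and g.ki != st.last_ki:
            st.integral *= st.last_ki / g.ki
        st.last_ki = g.ki
        error = sign * (setpoint - measurement)
        if not np.isfinite(error):
            st.fault = True
            return st.prev_output
        st.fault = False
        deriv = 0.0
        if st.prev_measurement is not None and g.kd > 0:
            deriv = -g.kd * sign * (measurement - st.prev_measurement) / dt
        candidate_integral = st.integral + error * dt
        u_raw = g.kp * error + g.ki * candidate_integral + deriv
        u = float(np.clip(u_raw, 0.0, self.i_max))
        saturated = u_raw != u
        if self.antiwindup and saturated and (
                (u_raw > self.i_max and error > 0) or (u_raw < 0.0 and error < 0)):
            pass                      # freeze the integral
        else:
            st.integral = candidate_integral
        st.prev_measurement = measurement
        st.prev_output = u
        return u


@dataclass
class GainSchedule:
    """The value–gain matrix: PID gains per operating point, linearly blended.

    Operating points are values of the scheduling variable (the measured
    normalised intensity, in [0, 1]); between points each gain interpolates
    piecewise-linearly, beyond the ends it clamps.
    """

    operating_points: list
    gains: list                      # list[PIDGains], aligned

    def __post_init__(self):
        op = np.asarray(self.operating_points, float)
        if len(op) != len(self.gains) or len(op) < 2:
            raise ValueError("need >=2 aligned operating points and gain sets")
        if np.any(np.diff(op) <= 0) or op[0] < 0 or op[-1] > 1:
            raise ValueError("operating points must be strictly increasing in [0,1]")

    def to_config(self) -> dict:
        return {"operating_points": [float(x) for x in self.operating_points],
                "gains": [{"kp": g.kp, "ki": g.ki, "kd": g.kd} for g in self.gains]}

    @classmethod
    def from_config(cls, cfg: dict) -> "GainSchedule":
        return cls(list(cfg["operating_points"]),
                   [PIDGains(**g) for g in cfg["gains"]])


def schedule_gains(measurement: float, schedule: GainSchedule) -> PIDGains:
    """Interpolate the gain matrix at the (clipped) scheduling variable."""
    x = float(np.clip(measurement, 0.0, 1.0))
    op = np.asarray(schedule.operating_points, float)
    kp = float(np.interp(x, op, [g.kp for g in schedule.gains]))
    ki = float(np.interp(x, op, [g.ki for g in schedule.gains]))
    kd = float(np.interp(x, op, [g.kd for g in schedule.gains]))
    return PIDGains(kp, ki, kd)


class SchedulingVariable:
    """Temporally smoothed scheduling input: 3-frame moving average.

    Gain chatter from frame-to-frame measurement noise is suppressed by
    scheduling on a short moving average of the (already temporally
    filtered) measurement.
    """

    def __init__(self, window: int = 3):
        self._buf: list[float] = []
        self.window = window

    def update(self, value: float) -> float:
        self._buf.append(float(value))
        if len(self._buf) > self.window:
            self._buf.pop(0)
        return float(np.mean(self._buf))
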
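"""Closed-loop experiment runner.

Each frame runs the full loop the platform executes on hardware:
acquire → segment/track → measure → control → illuminate → plant responds.
Everything is seeded and the record is reproducible bit-exactly from
config + seed.

Two experiment families:

* ``migration`` — cells guided around circular paths by the trajectory
  controller (one cell per field-of-view tile; optionally a shared field
  with collision avoidance), 60 s frames.
* ``lexy`` / ``multi_lexy`` — nucleocytoplasmic titration by (gain-scheduled)
  PID, 15 s frames; ``multi_lexy`` drives all nuclei at the hardware
  irradiance via pulse-width modulation, each with its own duty cycle.
"""

from __future__ import annotations

import importlib.resources
import math
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import vision
from .control import (GainSchedule, MigrationControllerConfig, PIDController,
                      PIDGains, AvoidanceConfig, SchedulingVariable,
                      apply_avoidance, detect_collision, direction_sign,
                      migration_controller_step, schedule_gains)
from .geometry import GuidePath, circle_path, project_to_path
from .metrics import loop_deviation_summary, steady_state_error
from .microscope import (Frame, IlluminationCommand, LexyGeometry, Optics,
                         SimulatedMicroscope, illumination_log)
from .plants import (LexyPlant, MigratingCell, PopulationSpec, lexy_step,
                     migrate_step, sample_population)

__all__ = [
    "ExperimentConfig",
    "LoopRecord",
    "run_closed_loop",
    "summarise_migration",
    "summarise_lexy",
    "default_gain_schedule",
]

DEFAULT_INTERVALS = {"migration": 60.0, "lexy": 15.0, "multi_lexy": 15.0}
DEFAULT_HETEROGENEITY = {
    "migration": {"speed_base": (0.3, 0.3), "expression": (30000.0, 0.3)},
    "lexy": {"expression": (1.0, 0.3)},
}


@dataclass
class ExperimentConfig:
    """Full description of one closed-loop experiment.

    ``heterogeneity`` maps plant parameter names to (mean, cv) of a
    log-normal population draw; ``setpoints`` is the staircase as
    (frame, setpoint) pairs in normalised-intensity units.
    """

    mode: str = "migration"
    n_frames: int = 60
    frame_interval: float | None = None          # s; per-mode default
    seed: int = 0
    n_cells: int = 1
    heterogeneity: dict | None = None
    noise: bool = True
    # migration
    path_radius: float = 40.0                    # µm
    lookahead: float = 6.0                       # µm
    front_fraction: float = 0.5
    irradiance: float = 0.23                     # µW/cm²
    light_on: bool = True
    avoidance: bool = False
    avoidance_horizon: int = 5
    collision_distance: float = 30.0             # µm
    paths: list | None = None                    # explicit path configs (shared FOV)
    start_positions: list | None = None
    # lexy
    control_mode: str = "cytosol"                # "cytosol" | "nucleus"
    controller: str = "scheduled"                # "pid" | "scheduled" | "none"
    gains: dict | None = None                    # fixed-PID gains
    schedule: dict | None = None                 # value–gain matrix config
    setpoints: list = field(default_factory=lambda: [(0, 0.5)])
    i_max: float = 10.4                          # µW/cm²
    pwm: bool = False
    temporal_filter: str = "hold"
    contrast_threshold: float = 0.05
    # optics
    tile_px: int | None = None
    pixel_size: float = 1.0                      # µm/px
    psf_sigma: float = 1.5                       # px
    background: float = 100.0
    read_noise: float = 2.0

    def __post_init__(self):
        if self.mode not in ("migration", "lexy", "multi_lexy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.frame_interval is None:
            self.frame_interval = DEFAULT_INTERVALS[self.mode]
        if self.frame_interval <= 0 or self.n_frames < 1 or self.n_cells < 1:
            raise ValueError("interval, n_frames and n_cells must be positive")
        if self.heterogeneity is None:
            kind = "migration" if self.mode == "migration" else "lexy"
            self.heterogeneity = dict(DEFAULT_HETEROGENEITY[kind])
        if self.tile_px is None:
            self.tile_px = 128 if self.mode == "migration" else 64
        if self.mode == "multi_lexy":
            self.pwm = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._plain(), fh, sort_keys=False)

    def _plain(self) -> dict:
        d = asdict(self)
        d["heterogeneity"] = {k: list(v) for k, v in self.heterogeneity.items()}
        d["setpoints"] = [list(sp) for sp in self.setpoints]
        return d

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "heterogeneity" in d and d["heterogeneity"] is not None:
            d["heterogeneity"] = {k: tuple(v) for k, v in d["heterogeneity"].items()}
        if "setpoints" in d:
            d["setpoints"] = [tuple(sp) for sp in d["setpoints"]]
        return cls(**d)


@dataclass
class LoopRecord:
    """Per-frame log of one closed-loop run plus the config snapshot."""

    df: pd.DataFrame
    config: ExperimentConfig
    events: list
    frame_times: list                 # wall-clock s per frame (not in the CSVs)
    paths: list | None = None         # per-cell GuidePath (migration)
    commands: list = field(default_factory=list)
    calibrations: dict | None = None  # per-cell CompartmentCalibration (lexy)

    def save(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.df.to_csv(out / "tracks.csv", index=False)
        if self.commands:
            illumination_log(self.commands, out / "commands.csv")
        (out / "events.log").write_text("\n".join(self.events) + "\n"
                                        if self.events else "")
        pd.DataFrame({"frame": range(len(self.frame_times)),
                      "wall_s": self.frame_times}).to_csv(
            out / "timing.csv", index=False)


def default_gain_schedule() -> GainSchedule:
    """The packaged value–gain matrix, tuned against the default plant."""
    ref = importlib.resources.files("optoloop.data") / "default_gain_schedule.yaml"
    return GainSchedule.from_config(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _grid_layout(n: int, tile_px: int, pixel_size: float):
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    shape = (rows * tile_px, cols * tile_px)
    centers = []
    for i in range(n):
        r, c = divmod(i, cols)
        centers.append(np.array([(c + 0.5) * tile_px * pixel_size,
                                 (r + 0.5) * tile_px * pixel_size]))
    return shape, centers


def _merge_commands(commands: dict, n_cells: int, interval: float,
                    shape) -> IlluminationCommand:
    masks, irr, duty, rids = [], [], [], []
    for i in range(n_cells):
        cmd = commands.get(i)
        if cmd is None or not cmd.masks:
            continue
        masks.append(cmd.masks[0])
        irr.append(cmd.irradiances[0])
        duty.append(cmd.duty_cycles[0])
        rids.append(i)
    if not masks:
        return IlluminationCommand.dark(interval)
    return IlluminationCommand(masks, irr, duty, interval, rids)


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def _run_migration(cfg: ExperimentConfig) -> LoopRecord:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    if cfg.paths is not None:
        paths = [GuidePath.from_config(p) for p in cfg.paths]
        starts = [np.asarray(s, float) for s in cfg.start_positions]
        fov_um = max(float(np.max(p.vertices)) for p in paths) + 3 * cfg.path_radius
        side = int(math.ceil(fov_um / cfg.pixel_size / cfg.tile_px)) * cfg.tile_px
        shape = (side, side)
    else:
        shape, centers = _grid_layout(n, cfg.tile_px, cfg.pixel_size)
        paths = [circle_path(c, cfg.path_radius) for c in centers]
        starts = [c + np.array([cfg.path_radius, 0.0]) for c in centers]

    spec = PopulationSpec(n, "migration", cfg.heterogeneity, cfg.seed)
    template = MigratingCell(position=np.zeros(2), polarity=(1.0, 0.0))
    plants = sample_population(spec, template)
    for i, p in enumerate(plants):
        p.position = starts[i].copy()
        tangent = np.array([0.0, 1.0])       # circle tangent at angle 0
        if cfg.paths is not None:
            proj = project_to_path(p.position, paths[i])
            t2, _ = paths[i].point_at(proj.arc_position + 1.0), None
            tangent = t2 - proj.projected_point
            tangent = tangent / (np.linalg.norm(tangent) or 1.0)
        p.polarity = tangent

    optics = Optics(shape, cfg.pixel_size, cfg.psf_sigma, cfg.background,
                    cfg.read_noise)
    mic = SimulatedMicroscope(optics, "migration", rng if cfg.noise else None)
    mic.plants = plants
    tracker = vision.Tracker(max_step=4.0 * cfg.frame_interval / 60.0 + 10.0,
                             max_gap=2)
    ctrl_cfg = MigrationControllerConfig(cfg.lookahead, cfg.front_fraction,
                                         cfg.irradiance, cfg.frame_interval)
    avoid_cfg = AvoidanceConfig(cfg.avoidance_horizon, cfg.collision_distance)

    events: list = []
    rows, commands, frame_times = [], [], []
    track_to_cell: dict[int, int] = {}
    active_pullback: dict[int, tuple] = {}
    prev_aoi: dict[int, np.ndarray | None] = {i: None for i in range(n)}

    tiled = cfg.paths is None
    cols = int(math.ceil(math.sqrt(n))) if tiled else 0

    for k in range(cfg.n_frames):
        t0 = time.perf_counter()
        mic.time = k * cfg.frame_interval
        frame = mic.acquire()

        # cell -> (measured centroid µm, full-frame mask, track id)
        detections: dict[int, tuple] = {}
        if tiled:
            # one cell per stage position: segment each tile independently so
            # a dim cell is thresholded against its own tile statistics, and
            # identity follows the tile
            for i in range(n):
                r, c = divmod(i, cols)
                sl = (slice(r * cfg.tile_px, (r + 1) * cfg.tile_px),
                      slice(c * cfg.tile_px, (c + 1) * cfg.tile_px))
                tile = Frame(frame.pixels[sl], frame.pixel_size,
                             frame.timestamp)
                tseg = vision.segment_frame(tile, "whole-cell")
                if not tseg.labels:
                    continue
                lab = max(tseg.labels, key=lambda l: tseg.areas[l])
                off = np.array([sl[1].start * cfg.pixel_size,
                                sl[0].start * cfg.pixel_size])
                gmask = np.zeros(shape, dtype=bool)
                gmask[sl] = tseg.label_mask == lab
                detections[i] = (np.asarray(tseg.centroids[lab]) + off,
                                 gmask, i + 1)
        else:
            seg = vision.segment_frame(frame, "whole-cell")
            assignment = tracker.update(seg, k)
            if k == 0:
                for tid, lab in assignment.items():
                    c = np.asarray(seg.centroids[lab])
                    track_to_cell[tid] = int(np.argmin(
                        [np.linalg.norm(c - s) for s in starts]))
            for tid, lab in assignment.items():
                if tid in track_to_cell:
                    detections[track_to_cell[tid]] = (
                        np.asarray(seg.centroids[lab]),
                        seg.label_mask == lab, tid)

        cmds: dict[int, IlluminationCommand] = {}
        projections: dict[int, object] = {}
        for i in range(n):
            if i not in detections:
                events.append(f"frame {k}: cell {i} lost; light off")
                cmds[i] = IlluminationCommand.dark(cfg.frame_interval)
                projections[i] = None
                continue
            centroid, mask, _ = detections[i]
            cmd, proj, _ = migration_controller_step(
                centroid, mask, paths[i], ctrl_cfg, cfg.pixel_size,
                prev_aoi[i], events)
            if cmd.masks:
                prev_aoi[i] = cmd.masks[0]
            cmds[i] = cmd
            projections[i] = proj

        if cfg.avoidance and not tiled and len(tracker.tracks) >= 2:
            positions = {track_to_cell[t]: tr.centroid
                         for t, tr in tracker.tracks.items() if t in track_to_cell}
            velocities = {track_to_cell[t]: tr.velocity
                          for t, tr in tracker.tracks.items() if t in track_to_cell}
            masks = {i: det[1] for i, det in detections.items()}
            flagged = detect_collision(positions, velocities, avoid_cfg)
            # pullback hysteresis: a yielder keeps retreating along its
            # captured rear direction until the pair separates again
            for a, b in flagged:
                y, other = (a, b) if a <= b else (b, a)
                if y not in active_pullback:
                    v = np.asarray(velocities[y], float)
                    rear = (-v / np.linalg.norm(v)
                            if np.linalg.norm(v) > 0 else np.array([1.0, 0.0]))
                    active_pullback[y] = (other, rear)
            release = 1.5 * cfg.collision_distance
            for y in list(active_pullback):
                partner, _ = active_pullback[y]
                if (y not in positions or partner not in positions
                        or np.linalg.norm(positions[y] - positions[partner])
                        > release):
                    del active_pullback[y]
            cmds = apply_avoidance(cmds, flagged, positions, velocities, masks,
                                   cfg.front_fraction, cfg.pixel_size,
                                   events=events,
                                   forced={y: d for y, (_, d)
                                           in active_pullback.items()})

        full = (_merge_commands(cmds, n, cfg.frame_interval, shape)
                if cfg.light_on else IlluminationCommand.dark(cfg.frame_interval))
        mic.illuminate(full)
        commands.append(full)
        doses = mic.plant_doses(full)

        region_of = {rid: j for j, rid in enumerate(full.region_ids)}
        for i in range(n):
            dose = float(doses[i]) if len(doses) else 0.0
            aoi_dir = None
            j = region_of.get(i)
            if j is not None and full.masks[j].any():
                rr, cc = np.nonzero(full.masks[j])
                aoi_c = np.array([cc.mean() * cfg.pixel_size,
                                  rr.mean() * cfg.pixel_size])
                aoi_dir = aoi_c - plants[i].position
            plants[i] = migrate_step(plants[i], dose, aoi_dir,
                                     cfg.frame_interval,
                                     rng if cfg.noise else None)

        for i in range(n):
            det = detections.get(i)
            proj = projections.get(i)
            rows.append({
                "frame": k, "time_s": k * cfg.frame_interval, "cell": i,
                "track_id": det[2] if det else -1,
                "x_um": det[0][0] if det else np.nan,
                "y_um": det[0][1] if det else np.nan,
                "true_x_um": plants[i].position[0],
                "true_y_um": plants[i].position[1],
                "deviation_um": proj.deviation if proj else np.nan,
                "arc_position_um": proj.arc_position if proj else np.nan,
                "irradiance_uW_cm2": float(doses[i]) if len(doses) else 0.0,
            })
        mic.plants = plants
        frame_times.append(time.perf_counter() - t0)

    df = pd.DataFrame(rows)
    return LoopRecord(df, cfg, events, frame_times, paths, commands)


# ---------------------------------------------------------------------------
# LEXY titration
# ---------------------------------------------------------------------------

def _measure_cells(mic: SimulatedMicroscope, cell_centers, params,
                   calibrations=None, contrast_threshold=0.05):
    """Acquire marker+reporter, segment, and measure each cell's compartments.

    Segmentation runs on the marker channel; intensities are measured on the
    reporter channel with its own background estimate.  Returns
    (seg, {cell: measurement-or-raw-means}).
    """
    marker = mic.acquire("marker")
    reporter = mic.acquire("reporter")
    seg = vision.segment_frame(marker, "nucleus+cytosol", params)
    seg_r = replace(seg, background=vision._background(
        reporter.pixels, seg.label_mask > 0)[0])
    out = {}
    for lab in seg.labels:
        c = np.asarray(seg.centroids[lab])
        cell = int(np.argmin([np.linalg.norm(c - cc) for cc in cell_centers]))
        if calibrations is None:
            out[cell] = vision._compartment_means(reporter, seg_r, lab)
        else:
            out[cell] = vision.measure_compartments(
                reporter, seg_r, lab, calibrations[cell],
                contrast_threshold)
    return seg, out


def _calibrate(mic, plants, geometries, centers, params, i_max, rng,
               n_frames: int = 3):
    """Pre-run dynamic-range calibration from dark and saturating-light states."""
    dark = {i: [] for i in range(len(plants))}
    light = {i: [] for i in range(len(plants))}
    saved = list(mic.plants)
    for i in range(n_frames):
        _, m = _measure_cells(mic, centers, params)
        for cell, means in m.items():
            if means is not None:
                dark[cell].append(means)
    lit = [lexy_step(p, i_max, 1800.0) for p in plants]
    mic.plants = lit
    for i in range(n_frames):
        _, m = _measure_cells(mic, centers, params)
        for cell, means in m.items():
            if means is not None:
                light[cell].append(means)
    mic.plants = saved
    return {i: vision.calibrate_range(dark[i], light[i])
            for i in range(len(plants))}


def _setpoint_at(setpoints, frame: int) -> float:
    sp = setpoints[0][1]
    for f, s in setpoints:
        if frame >= f:
            sp = s
    return sp


def _run_lexy(cfg: ExperimentConfig) -> LoopRecord:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    shape, centers = _grid_layout(n, cfg.tile_px, cfg.pixel_size)
    geometries = [LexyGeometry(c) for c in centers]
    spec = PopulationSpec(n, "lexy", cfg.heterogeneity, cfg.seed)
    plants = sample_population(spec, LexyPlant())

    optics = Optics(shape, cfg.pixel_size, cfg.psf_sigma, cfg.background,
                    cfg.read_noise, cfg.i_max)
    mic = SimulatedMicroscope(optics, "lexy", rng if cfg.noise else None,
                              geometries)
    mic.plants = plants
    params = vision.SegmentationParams()
    calibrations = _calibrate(mic, plants, geometries, centers, params,
                              cfg.i_max, rng)

    sign = direction_sign(cfg.control_mode)
    schedule = None
    if cfg.controller == "scheduled":
        schedule = (GainSchedule.from_config(cfg.schedule)
                    if cfg.schedule else default_gain_schedule())
        mid_gains = schedule_gains(0.5, schedule)
    elif cfg.controller == "pid":
        mid_gains = (PIDGains(**cfg.gains) if cfg.gains
                     else schedule_gains(0.5, default_gain_schedule()))
    else:
        mid_gains = PIDGains(1.0, 0.0, 0.0)
    pids = [PIDController(mid_gains, cfg.i_max) for _ in range(n)]
    filters = [vision.TemporalFilter(cfg.temporal_filter) for _ in range(n)]
    sched_vars = [SchedulingVariable() for _ in range(n)]

    events: list = []
    rows, commands, frame_times = [], [], []
    for k in range(cfg.n_frames):
        t0 = time.perf_counter()
        mic.time = k * cfg.frame_interval
        setpoint = _setpoint_at(cfg.setpoints, k)
        seg, measured = _measure_cells(mic, centers, params, calibrations,
                                       cfg.contrast_threshold)
        label_of = {}
        for lab in seg.labels:
            c = np.asarray(seg.centroids[lab])
            label_of[int(np.argmin([np.linalg.norm(c - cc)
                                    for cc in centers]))] = lab

        cmds: dict[int, IlluminationCommand] = {}
        for i in range(n):
            meas = measured.get(i)
            raw = np.nan
            if meas is not None and meas.valid:
                raw = (meas.normalised_cytosol if cfg.control_mode == "cytosol"
                       else meas.normalised_nucleus)
            filtered = filters[i].update(
                raw, meas is not None and meas.valid and meas.contrast_ok
                and np.isfinite(raw))
            if filtered is None:
                events.append(f"frame {k}: cell {i} no valid measurement yet; "
                              "controller deferred")
                cmds[i] = IlluminationCommand.dark(cfg.frame_interval)
                rows.append(_lexy_row(k, cfg, i, setpoint, meas, np.nan,
                                      np.nan, 0.0, 0.0))
                continue
            # the value–gain matrix is indexed by the cytosolic operating
            # point; under nucleus control the conserved total makes the
            # normalised nucleus its mirror image
            op_value = filtered if cfg.control_mode == "cytosol" else 1.0 - filtered
            gains = (schedule_gains(sched_vars[i].update(op_value), schedule)
                     if schedule is not None else None)
            if cfg.controller == "none":
                u = 0.0
            else:
                u = pids[i].step(setpoint, filtered, cfg.frame_interval,
                                 sign, gains)
            lab = label_of.get(i)
            if lab is None or seg.nucleus_mask is None \
                    or not (seg.nucleus_mask == lab).any():
                cmds[i] = IlluminationCommand.dark(cfg.frame_interval)
            else:
                mask = seg.nucleus_mask == lab
                if cfg.pwm:
                    cmds[i] = IlluminationCommand(
                        [mask], [cfg.i_max], [u / cfg.i_max],
                        cfg.frame_interval)
                else:
                    cmds[i] = IlluminationCommand(
                        [mask], [u], [1.0], cfg.frame_interval)
            err = sign * (setpoint - filtered)
            rows.append(_lexy_row(k, cfg, i, setpoint, meas, filtered, err,
                                  u, cmds[i].duty_cycles[0] if cmds[i].masks
                                  else 0.0))

        full = _merge_commands(cmds, n, cfg.frame_interval, shape)
        mic.illuminate(full)
        commands.append(full)
        doses = mic.plant_doses(full)
        plants = [lexy_step(p, float(doses[i]) if len(doses) else 0.0,
                            cfg.frame_interval)
                  for i, p in enumerate(plants)]
        mic.plants = plants
        frame_times.append(time.perf_counter() - t0)

    df = pd.DataFrame(rows)
    return LoopRecord(df, cfg, events, frame_times, None, commands,
                      calibrations)


def _lexy_row(k, cfg, i, setpoint, meas, filtered, err, u, duty):
    valid = meas is not None and meas.valid
    return {
        "frame": k, "time_s": k * cfg.frame_interval, "cell": i,
        "setpoint": setpoint,
        "nucleus_mean": meas.nucleus_mean if valid else np.nan,
        "cytosol_mean": meas.cytosol_mean if valid else np.nan,
        "normalised_nucleus": meas.normalised_nucleus if valid else np.nan,
        "normalised_cytosol": meas.normalised_cytosol if valid else np.nan,
        "contrast_ok": bool(meas.contrast_ok) if valid else False,
        "measurement": filtered, "error": err,
        "irradiance_uW_cm2": u, "duty": duty,
    }


def run_closed_loop(config: ExperimentConfig) -> LoopRecord:
    """Execute a full closed-loop experiment; deterministic given config+seed."""
    if config.mode == "migration":
        return _run_migration(config)
    return _run_lexy(config)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarise_migration(record: LoopRecord) -> pd.DataFrame:
    """Per-cell deviation/speed summary recomputed from recorded centroids."""
    out = []
    for i, path in enumerate(record.paths):
        sub = record.df[record.df.cell == i].dropna(subset=["x_um"])
        cent = sub[["x_um", "y_um"]].to_numpy()
        dev = sub["deviation_um"].to_numpy()
        loops = loop_deviation_summary(cent, path,
                                       record.config.frame_interval) \
            if path.closed and len(cent) > 1 else pd.DataFrame()
        out.append({
            "cell": i,
            "mean_deviation_um": float(np.nanmean(dev)),
            "max_deviation_um": float(np.nanmax(dev)),
            "n_loops": int(len(loops)),
            "mean_projected_speed_um_min":
                float(loops["mean_projected_speed_um_min"].mean())
                if len(loops) else np.nan,
        })
    return pd.DataFrame(out)


def summarise_lexy(record: LoopRecord, smoothing: int = 5) -> pd.DataFrame:
    """Per-cell, per-epoch steady-state error (% of dynamic range)."""
    cfg = record.config
    bounds = [f for f, _ in cfg.setpoints] + [cfg.n_frames]
    out = []
    for i in sorted(record.df.cell.unique()):
        sub = record.df[record.df.cell == i]
        sig = sub["measurement"].to_numpy()
        for e in range(len(cfg.setpoints)):
            f0, f1 = bounds[e], bounds[e + 1]
            if f1 - f0 <= smoothing + 1:
                continue
            epoch = sig[f0:f1]
            sp = cfg.setpoints[e][1]
            res = steady_state_error(epoch, sp, smoothing, dynamic_range=1.0)
            out.append({"cell": int(i), "epoch": e, "setpoint": sp,
                        "settled": res.settled,
                        "steady_state_error_pct":
                            100.0 * res.mean_abs_error
                            if res.settled else np.nan})
    return pd.DataFrame(out)
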
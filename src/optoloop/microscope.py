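"""Virtual microscope: synthetic fluorescence rendering and patterned illumination.

Implements the abstract microscope contract (acquire / illuminate) with a
simulated backend that renders plant states into noisy fluorescence frames and
turns :class:`IlluminationCommand` patterns — per-region binary masks with an
irradiance and a PWM duty cycle — into the effective light dose each plant
receives.  A hardware backend (DMD + camera) could satisfy the same contract.

Pixel convention: 0-based (row, col); stage x maps to columns and y to rows
via the pixel size only (no rotation).  Camera model: Poisson shot noise on
signal + background, additive Gaussian read noise, gain 1 count/photon.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Optics",
    "Frame",
    "IlluminationCommand",
    "MicroscopeInterface",
    "SimulatedMicroscope",
    "LexyGeometry",
    "render_migration_frame",
    "render_lexy_frame",
    "apply_illumination",
    "pwm_segments",
    "write_stack",
    "read_stack",
    "mask_to_rle",
    "rle_to_mask",
]


@dataclass(frozen=True)
class Optics:
    """Camera/objective parameters of the virtual microscope."""

    shape: tuple = (128, 128)       # (rows, cols) px
    pixel_size: float = 1.0         # µm/px
    psf_sigma: float = 1.5          # px, Gaussian PSF
    background: float = 100.0       # counts
    read_noise: float = 2.0         # counts RMS
    i_max: float = 10.4             # µW/cm², hardware irradiance ceiling


@dataclass
class Frame:
    """One acquired image."""

    pixels: np.ndarray              # counts, non-negative
    pixel_size: float               # µm/px
    timestamp: float = 0.0          # s
    channel: str = "reporter"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class IlluminationCommand:
    """Patterned illumination for one frame interval.

    One binary mask per controlled region, with a per-region irradiance
    (µW/cm²) and a PWM duty cycle in [0, 1].  The effective dose of a region
    over the interval is ``duty × irradiance`` (fast-PWM limit).
    """

    masks: list                      # list of 2-D bool arrays
    irradiances: list                # µW/cm² per region
    duty_cycles: list | None = None  # defaults to all-1
    frame_interval: float = 60.0     # s
    region_ids: list | None = None

    def __post_init__(self):
        if self.duty_cycles is None:
            self.duty_cycles = [1.0] * len(self.masks)
        if self.region_ids is None:
            self.region_ids = list(range(len(self.masks)))
        if not (len(self.masks) == len(self.irradiances) == len(self.duty_cycles)):
            raise ValueError("masks, irradiances and duty_cycles must align")
        for I in self.irradiances:
            if I < 0:
                raise ValueError("irradiance must be >= 0")
        for d in self.duty_cycles:
            if not 0.0 <= d <= 1.0:
                raise ValueError("duty cycle must lie in [0, 1]")

    @classmethod
    def dark(cls, frame_interval: float = 60.0) -> "IlluminationCommand":
        """Light-off command."""
        return cls(masks=[], irradiances=[], frame_interval=frame_interval)

    def validate_against(self, optics: Optics) -> None:
        for m in self.masks:
            if m.shape != optics.shape:
                raise ValueError("mask shape does not match frame bounds")
        for I in self.irradiances:
            if I > optics.i_max:
                raise ValueError("irradiance exceeds hardware maximum")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disc(shape, center_px, radius_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px ** 2


def _finish(signal: np.ndarray, optics: Optics,
            rng: np.random.Generator | None, timestamp: float, channel: str) -> Frame:
    img = ndimage.gaussian_filter(signal, optics.psf_sigma) + optics.background
    if rng is not None:
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        img += rng.normal(0.0, optics.read_noise, img.shape)
        img = np.maximum(img, 0.0)
    return Frame(img, optics.pixel_size, timestamp, channel)


def render_migration_frame(cells, optics: Optics,
                           rng: np.random.Generator | None = None,
                           timestamp: float = 0.0,
                           events: list | None = None) -> Frame:
    """Render migrating cells as PSF-blurred discs.

    Each cell's background-corrected integrated intensity equals its
    ``expression`` (gain 1); cells fully outside the field of view are
    omitted with a warning event.
    """
    signal = np.zeros(optics.shape, dtype=float)
    ps = optics.pixel_size
    for i, c in enumerate(cells):
        row, col = c.position[1] / ps, c.position[0] / ps
        r_px = c.shape_radius / ps
        if (row + r_px < 0 or col + r_px < 0
                or row - r_px > optics.shape[0] or col - r_px > optics.shape[1]):
            if events is not None:
                events.append(f"cell {i} outside field of view, omitted")
            continue
        disc = _disc(optics.shape, (row, col), r_px)
        n_px = disc.sum()
        if n_px:
            signal[disc] += c.expression / n_px
    return _finish(signal, optics, rng, timestamp, "reporter")


@dataclass
class LexyGeometry:
    """Compartment geometry for rendering one LEXY cell."""

    center: np.ndarray              # µm
    cell_radius: float = 18.0       # µm
    nucleus_radius: float = 8.0     # µm

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise ValueError("need 0 < nucleus_radius < cell_radius")


# reporter counts per (concentration × expression) unit; marker levels are
# fixed so the marker channel always segments regardless of reporter state
REPORTER_GAIN = 200.0
MARKER_NUCLEUS = 600.0
MARKER_CYTO = 150.0


def render_lexy_frame(plants, geometries, optics: Optics,
                      rng: np.random.Generator | None = None,
                      timestamp: float = 0.0, channel: str = "reporter") -> Frame:
    """Render LEXY cells: nucleus disc inside a cell disc.

    ``reporter`` channel: nucleus pixels ∝ E·N, cytosol ring ∝ E·C (the
    measured channel).  ``marker`` channel: constant bright nucleus over a dim
    cell body — a segmentation channel akin to a nuclear marker line.
    """
    signal = np.zeros(optics.shape, dtype=float)
    ps = optics.pixel_size
    for p, g in zip(plants, geometries):
        row, col = g.center[1] / ps, g.center[0] / ps
        cell = _disc(optics.shape, (row, col), g.cell_radius / ps)
        nuc = _disc(optics.shape, (row, col), g.nucleus_radius / ps)
        cyto = cell & ~nuc
        if channel == "reporter":
            signal[nuc] += REPORTER_GAIN * p.expression * p.N
            signal[cyto] += REPORTER_GAIN * p.expression * p.C
        elif channel == "marker":
            signal[nuc] += MARKER_NUCLEUS
            signal[cyto] += MARKER_CYTO
        else:
            raise ValueError(f"unknown channel {channel!r}")
    return _finish(signal, optics, rng, timestamp, channel)


# ---------------------------------------------------------------------------
# illumination
# ---------------------------------------------------------------------------

def apply_illumination(command: IlluminationCommand, positions, radii,
                       optics: Optics, scatter_fraction: float = 0.0,
                       halo_radius: float = 0.0) -> np.ndarray:
    """Effective mean irradiance (µW/cm²) each plant receives this interval.

    A plant is hit by a region when the region's mask overlaps the plant's
    sensitive footprint (a disc of the given radius); it then receives the
    region's ``duty × irradiance``.  With scattering on, plants whose
    footprint lies within ``halo_radius`` of a mask (but not on it) receive
    ``scatter_fraction`` of that region's dose — the unintended activation of
    close neighbours.
    """
    command.validate_against(optics)
    ps = optics.pixel_size
    out = np.zeros(len(positions))
    for mask, I, duty in zip(command.masks, command.irradiances, command.duty_cycles):
        if not mask.any():
            continue
        rows, cols = np.nonzero(mask)
        mx, my = cols * ps, rows * ps   # pixel centres in stage µm
        dose = duty * I
        for j, (pos, rad) in enumerate(zip(positions, radii)):
            d = np.hypot(mx - pos[0], my - pos[1]).min()
            if d <= rad:
                out[j] += dose
            elif scatter_fraction > 0 and d <= rad + halo_radius:
                out[j] += scatter_fraction * dose
    return out


def pwm_segments(irradiance: float, duty: float, frame_interval: float,
                 period: float) -> list:
    """Explicit slow-PWM on/off schedule for one frame interval.

    Returns ``[(irradiance_or_0, duration_s), ...]`` covering the interval.
    Used to check the fast-PWM (time-averaged) approximation against an
    explicit switching drive.
    """
    if not 0.0 <= duty <= 1.0:
        raise ValueError("duty must lie in [0, 1]")
    if period <= 0 or frame_interval <= 0:
        raise ValueError("period and interval must be positive")
    segs = []
    t = 0.0
    while t < frame_interval - 1e-12:
        on = min(duty * period, frame_interval - t)
        if on > 0:
            segs.append((irradiance, on))
        t += on
        off = min((1.0 - duty) * period, frame_interval - t)
        if off > 0:
            segs.append((0.0, off))
        t += off
        if duty in (0.0, 1.0):
            break
    return segs


# ---------------------------------------------------------------------------
# microscope contract
# ---------------------------------------------------------------------------

class MicroscopeInterface(abc.ABC):
    """Contract every backend (simulated or hardware bridge) satisfies."""

    @abc.abstractmethod
    def acquire(self, channel: str = "reporter") -> Frame:
        """Capture one frame of the current sample state."""

    @abc.abstractmethod
    def illuminate(self, command: IlluminationCommand) -> np.ndarray:
        """Apply a patterned-light command; returns duty × irradiance per region."""


class SimulatedMicroscope(MicroscopeInterface):
    """Renders plant states; the sample is the plant list the runner updates."""

    def __init__(self, optics: Optics, mode: str = "migration",
                 rng: np.random.Generator | None = None,
                 geometries: list | None = None,
                 scatter_fraction: float = 0.0, halo_radius: float = 0.0):
        if mode not in ("migration", "lexy"):
            raise ValueError(f"unknown mode {mode!r}")
        self.optics = optics
        self.mode = mode
        self.rng = rng
        self.geometries = geometries
        self.scatter_fraction = scatter_fraction
        self.halo_radius = halo_radius
        self.plants: list = []
        self.time: float = 0.0
        self.last_command: IlluminationCommand | None = None
        self.events: list = []

    def acquire(self, channel: str = "reporter") -> Frame:
        if self.mode == "migration":
            return render_migration_frame(self.plants, self.optics, self.rng,
                                          self.time, self.events)
        return render_lexy_frame(self.plants, self.geometries, self.optics,
                                 self.rng, self.time, channel)

    def illuminate(self, command: IlluminationCommand) -> np.ndarray:
        command.validate_against(self.optics)
        self.last_command = command
        return np.array([d * I for d, I in
                         zip(command.duty_cycles, command.irradiances)])

    def plant_doses(self, command: IlluminationCommand) -> np.ndarray:
        """Effective irradiance at each plant for this command."""
        if self.mode == "migration":
            positions = [p.position for p in self.plants]
            radii = [p.shape_radius for p in self.plants]
        else:
            positions = [g.center for g in self.geometries]
            radii = [g.nucleus_radius for g in self.geometries]
        return apply_illumination(command, positions, radii, self.optics,
                                  self.scatter_fraction, self.halo_radius)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_stack(frames, path) -> None:
    """Write frames as a multi-page 32-bit float TIFF."""
    tifffile.imwrite(path, np.stack([f.pixels.astype(np.float32) for f in frames]))


def read_stack(path, pixel_size: float, interval: float = 0.0) -> list:
    """Read a multi-page TIFF back into Frame objects."""
    arr = tifffile.imread(path)
    arr = arr[None] if arr.ndim == 2 else arr
    return [Frame(a.astype(float), pixel_size, i * interval) for i, a in enumerate(arr)]


def illumination_log(commands, path) -> None:
    """Per-frame illumination log CSV: frame, region, irradiance, duty."""
    rows = []
    for f, cmd in enumerate(commands):
        for rid, I, d in zip(cmd.region_ids, cmd.irradiances, cmd.duty_cycles):
            rows.append({"frame": f, "region_id": rid,
                         "irradiance_uW_cm2": I, "duty": d})
    pd.DataFrame(rows, columns=["frame", "region_id", "irradiance_uW_cm2",
                                "duty"]).to_csv(path, index=False)


def mask_to_rle(mask: np.ndarray) -> str:
    """Run-length encode a binary mask as plain text: 'rows cols: start,len ...'."""
    flat = np.asarray(mask, bool).ravel()
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flat.view(np.uint8), [0]])))
    runs = [f"{s},{e - s}" for s, e in zip(edges[::2], edges[1::2])]
    return f"{mask.shape[0]} {mask.shape[1]}: " + " ".join(runs)


def rle_to_mask(text: str) -> np.ndarray:
    head, _, body = text.partition(":")
    rows, cols = map(int, head.split())
    mask = np.zeros(rows * cols, dtype=bool)
    for token in body.split():
        s, n = map(int, token.split(","))
        mask[s: s + n] = True
    return mask.reshape(rows, cols)
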
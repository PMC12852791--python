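"""Guide paths, projections, and trajectory metrics.

Stage coordinates are in µm with the origin at the field-of-view corner,
x to the right and y down, matching image (row, col) order after scaling
by the pixel size.  Paths are polylines; a "circle path" is a polygonised
circle (default 1° angular resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GuidePath",
    "PathProjection",
    "circle_path",
    "project_to_path",
    "projected_speed",
    "next_setpoint",
    "path_deviation_series",
]


class InvalidPathError(ValueError):
    """Raised for degenerate guide paths (fewer than 2 distinct vertices)."""


@dataclass(frozen=True)
class GuidePath:
    """An ordered sequence of setpoints a cell centroid should track.

    Parameters
    ----------
    vertices : (n, 2) array
        Path vertices in µm, stage coordinates.
    closed : bool
        If True the last vertex connects back to the first.
    """

    vertices: np.ndarray
    closed: bool = False
    arc_length_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise InvalidPathError("path needs >=2 two-dimensional vertices")
        seg = np.diff(v, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.all(seglen == 0):
            raise InvalidPathError("all path vertices coincide")
        if np.any(seglen == 0):
            # drop zero-length segments; keeps arc length strictly increasing
            keep = np.concatenate([[True], seglen > 0])
            v = v[keep]
            seg = np.diff(v, axis=0)
            seglen = np.hypot(seg[:, 0], seg[:, 1])
        object.__setattr__(self, "vertices", v)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        if self.closed:
            back = np.hypot(*(v[0] - v[-1]))
            arc = np.append(arc, arc[-1] + back) if back > 0 else arc
        object.__setattr__(self, "arc_length_index", arc)

    # -- segment view (closed paths get the wrap-around segment) ------------
    @property
    def _segments(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        if self.closed and not np.allclose(v[0], v[-1]):
            a = v
            b = np.vstack([v[1:], v[:1]])
        else:
            a, b = v[:-1], v[1:]
        return a, b

    @property
    def total_length(self) -> float:
        return float(self.arc_length_index[-1])

    def point_at(self, arc_position: float) -> np.ndarray:
        """Point at a given arc-length position (wraps if closed, clamps if open)."""
        L = self.total_length
        s = float(arc_position)
        s = s % L if self.closed else min(max(s, 0.0), L)
        arc = self.arc_length_index
        i = int(np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(arc) - 2))
        a, b = self._segments
        t = (s - arc[i]) / (arc[i + 1] - arc[i])
        return a[i] + t * (b[i] - a[i])

    # -- serialisation -------------------------------------------------------
    def to_config(self) -> dict:
        return {"vertices": self.vertices.tolist(), "closed": bool(self.closed)}

    @classmethod
    def from_config(cls, cfg: dict) -> "GuidePath":
        return cls(np.asarray(cfg["vertices"], float), closed=bool(cfg.get("closed", False)))

    @classmethod
    def from_csv(cls, path, closed: bool = False) -> "GuidePath":
        df = pd.read_csv(path)
        return cls(df[["x_um", "y_um"]].to_numpy(float), closed=closed)


@dataclass(frozen=True)
class PathProjection:
    """Nearest-point projection of a query point onto a guide path."""

    projected_point: np.ndarray  # µm
    arc_position: float          # µm along the path
    deviation: float             # µm, >= 0


def circle_path(center, radius: float, angular_resolution_deg: float = 1.0) -> GuidePath:
    """Polygonised circle, the standard closed guide path.

    The chord error at 1° resolution is radius·(1−cos(0.5°)) ≈ 4e-5·radius.
    """
    if radius <= 0:
        raise InvalidPathError("radius must be positive")
    n = max(3, int(round(360.0 / angular_resolution_deg)))
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    cx, cy = center
    pts = np.column_stack([cx + radius * np.cos(th), cy + radius * np.sin(th)])
    return GuidePath(pts, closed=True)


def project_to_path(point, path: GuidePath) -> PathProjection:
    """Global minimum-distance projection of ``point`` onto the polyline.

    Ties between equally near segments are broken toward the smallest arc
    position, so the result is deterministic.
    """
    p = np.asarray(point, dtype=float)
    a, b = path._segments
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p - a, ab) / denom
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - p, proj - p)
    i = int(np.argmin(d2))  # argmin returns the first (= smallest arc) minimum
    arc = path.arc_length_index
    s = arc[i] + t[i] * (arc[i + 1] - arc[i])
    if path.closed:
        s = s % path.total_length
    return PathProjection(proj[i], float(s), float(np.sqrt(d2[i])))


def _arc_delta(s0: float, s1: float, path: GuidePath) -> float:
    """Signed arc progress from s0 to s1; closed paths take the short way round."""
    d = s1 - s0
    if path.closed:
        L = path.total_length
        d = (d + L / 2) % L - L / 2
    return d


def projected_speed(centroids, path: GuidePath, interval_s: float) -> np.ndarray:
    """Per-step projected speed (µm/min), signed by the direction of arc progress.

    Element ``t`` is the arc-length distance between the projected positions of
    centroids ``t`` and ``t+1``, divided by the imaging interval.
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >=2 centroids")
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    s = np.array([project_to_path(p, path).arc_position for p in c])
    d = np.array([_arc_delta(s[i], s[i + 1], path) for i in range(len(s) - 1)])
    return d / (interval_s / 60.0)


def next_setpoint(projection: PathProjection, path: GuidePath, lookahead: float):
    """Target point ``lookahead`` µm further along the path.

    Returns ``(point, done)``; ``done`` is True when an open path is exhausted
    (the terminal vertex is then returned).
    """
    if lookahead <= 0:
        raise ValueError("lookahead must be positive")
    s = projection.arc_position + lookahead
    if not path.closed and s >= path.total_length:
        return path.vertices[-1].copy(), True
    return path.point_at(s), False


def path_deviation_series(centroids, path: GuidePath) -> np.ndarray:
    """Path deviation (distance to nearest point on the path) per timepoint."""
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    return np.array([project_to_path(p, path).deviation for p in c])
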
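"""Post-run quantification.

Implements the standard analysis battery: steady-state error with the
smoothed-derivative settling criterion, one-phase-decay kinetics fits, and
per-loop path-deviation / projected-speed summaries for guided migration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import GuidePath, project_to_path, _arc_delta

__all__ = [
    "SteadyStateResult",
    "steady_state_error",
    "OnePhaseDecayFit",
    "fit_one_phase_decay",
    "loop_deviation_summary",
]


@dataclass
class SteadyStateResult:
    settled: bool
    settling_index: int | None
    mean_abs_error: float | None


def _smoothed_derivative(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving-average of the finite-difference derivative."""
    d = np.gradient(y)
    if window <= 1:
        return d
    kernel = np.ones(window) / window
    pad = window // 2
    dp = np.pad(d, pad, mode="edge")
    return np.convolve(dp, kernel, mode="same")[pad: pad + len(d)]


def steady_state_error(signal, setpoint: float, smoothing: int = 5,
                       zero_tol_frac: float = 1e-3,
                       dynamic_range: float | None = None) -> SteadyStateResult:
    """Mean |error| after the settling point of one setpoint epoch.

    The settling index is the first point, after the epoch start, where the
    smoothed derivative of the signal changes sign or falls to (near) zero —
    i.e. where the setpoint is first reached — cleaning the error of the
    transition time.  ``zero_tol_frac`` scales the near-zero tolerance by the
    dynamic range (defaults to the signal's own span).
    """
    y = np.asarray(signal, float)
    if len(y) < max(smoothing + 1, 3):
        raise ValueError("epoch shorter than the smoothing window")
    if dynamic_range is None:
        dynamic_range = float(np.ptp(y)) or 1.0
    d = _smoothed_derivative(y, smoothing)
    tol = zero_tol_frac * dynamic_range
    idx = None
    for i in range(1, len(d)):
        if abs(d[i]) <= tol or d[i] * d[i - 1] < 0:
            idx = i
            break
    if idx is None:
        return SteadyStateResult(False, None, None)
    return SteadyStateResult(True, idx, float(np.mean(np.abs(y[idx:] - setpoint))))


@dataclass
class OnePhaseDecayFit:
    ok: bool
    k: float | None = None           # 1/time-unit of t
    y0: float | None = None
    plateau: float | None = None
    residual_rms: float | None = None
    message: str = ""


def fit_one_phase_decay(t, y) -> OnePhaseDecayFit:
    """Least-squares fit of ``y = plateau + (y0 − plateau)·exp(−k·t)``.

    The rate constant is constrained positive.  Constant (flat) series make
    k unidentifiable and are flagged rather than fitted.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 4 or np.any(np.diff(t) <= 0):
        raise ValueError("need >=4 points with strictly increasing t")
    span = float(np.ptp(y))
    if span == 0 or span < 1e-12 * max(1.0, abs(y[0])):
        return OnePhaseDecayFit(False, message="flat series: rate unidentifiable")

    def model(tt, k, y0, plateau):
        return plateau + (y0 - plateau) * np.exp(-k * tt)

    # initial guesses: endpoints for the levels, log-linear slope for the rate
    y0g, pg = y[0], y[-1]
    mid = y0g + (pg - y0g) * (1 - 1 / np.e)
    k0 = 1.0 / max(t[np.argmin(np.abs(y - mid))], t[1] - t[0])
    try:
        popt, _ = curve_fit(model, t, y, p0=[k0, y0g, pg],
                            bounds=([1e-12, -np.inf, -np.inf],
                                    [np.inf, np.inf, np.inf]), maxfev=10000)
    except (RuntimeError, ValueError) as e:
        return OnePhaseDecayFit(False, message=f"fit failed: {e}")
    res = y - model(t, *popt)
    return OnePhaseDecayFit(True, float(popt[0]), float(popt[1]),
                            float(popt[2]), float(np.sqrt(np.mean(res ** 2))))


def loop_deviation_summary(centroids, path: GuidePath,
                           interval_s: float) -> pd.DataFrame:
    """Per-loop deviation and projected-speed statistics on a closed path.

    Loop boundaries are wraps of the arc position (cumulative arc progress
    crossing multiples of the path length).  Returns one row per completed
    loop with mean/max deviation (µm) and mean projected speed (µm/min);
    empty (with ``completed=False`` nowhere) if no loop completes.
    """
    if not path.closed:
        raise ValueError("per-loop summary requires a closed path")
    c = np.asarray(centroids, float)
    projs = [project_to_path(p, path) for p in c]
    dev = np.array([p.deviation for p in projs])
    s = np.array([p.arc_position for p in projs])
    # unwrap cumulative arc progress
    cum = np.concatenate([[s[0]], s[0] + np.cumsum(
        [_arc_delta(s[i], s[i + 1], path) for i in range(len(s) - 1)])])
    L = path.total_length
    loop_idx = np.floor((cum - cum[0]) / L).astype(int)
    rows = []
    for loop in range(loop_idx.max()):
        sel = loop_idx == loop
        if not sel.any() or loop_idx.max() <= loop:
            continue
        d = dev[sel]
        i0, i1 = np.flatnonzero(sel)[[0, -1]]
        dt_min = (i1 - i0) * interval_s / 60.0
        speed = (cum[i1] - cum[i0]) / dt_min if dt_min > 0 else np.nan
        rows.append({"loop": loop, "n_frames": int(sel.sum()),
                     "mean_deviation_um": float(d.mean()),
                     "max_deviation_um": float(d.max()),
                     "mean_projected_speed_um_min": float(speed)})
    return pd.DataFrame(rows, columns=["loop", "n_frames", "mean_deviation_um",
                                       "max_deviation_um",
                                       "mean_projected_speed_um_min"])
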
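"""Quick-look figures for run records."""

from __future__ import annotations

import numpy as np


def plot_migration(record, cell: int = 0, ax=None):
    """Trajectory of one guided cell over its path, plus the deviation trace."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 4))
    sub = record.df[record.df.cell == cell]
    path = record.paths[cell]
    v = np.vstack([path.vertices, path.vertices[:1]]) if path.closed \
        else path.vertices
    ax[0].plot(v[:, 0], v[:, 1], "k--", lw=1, label="guide path")
    ax[0].plot(sub.x_um, sub.y_um, "-", lw=0.8, label="centroid")
    ax[0].set_aspect("equal")
    ax[0].set_xlabel("x (µm)")
    ax[0].set_ylabel("y (µm)")
    ax[0].invert_yaxis()
    ax[0].legend(frameon=False, fontsize=8)
    ax[1].plot(sub.time_s / 60.0, sub.deviation_um, lw=0.8)
    ax[1].set_xlabel("time (min)")
    ax[1].set_ylabel("path deviation (µm)")
    return ax


def plot_titration(record, ax=None):
    """Measured normalised intensity vs setpoint staircase, per cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for cell, sub in record.df.groupby("cell"):
        ax.plot(sub.time_s / 60.0, sub.measurement, lw=0.8, label=f"cell {cell}")
    sub0 = record.df[record.df.cell == record.df.cell.iloc[0]]
    ax.step(sub0.time_s / 60.0, sub0.setpoint, "k--", lw=1, where="post",
            label="setpoint")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalised intensity")
    ax.set_ylim(-0.05, 1.05)
    return ax
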
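"""Figure helpers: polar histograms, direction-coloured trajectories, profiles.

Figures are presentation side effects; nothing in the analysis reads them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comet_tracking import Track, average_direction, direction_color
from .intensity_quant import LineProfile
from .synthetic_scenes import SceneSpec


def polar_histogram(
    thetas_deg: Sequence[float], bin_width_deg: float, path: str | Path
) -> None:
    """Polar histogram of the angle metric θ over [0°, 180°]."""
    thetas = np.asarray(thetas_deg, dtype=float)
    n_bins = int(round(180.0 / bin_width_deg))
    counts, edges = np.histogram(thetas, bins=n_bins, range=(0.0, 180.0))
    centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)

    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centers, counts, width=np.deg2rad(bin_width_deg), edgecolor="k", alpha=0.8)
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    ax.set_title(r"comet orientation angle $\theta$")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def trajectory_figure(
    tracks: Sequence[Track], spec: SceneSpec, path: str | Path
) -> None:
    """Comet trajectories coloured by their average direction (HSV wheel)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for tr in tracks:
        if tr.n_points < 2:
            continue
        ang = average_direction(tr)
        color = direction_color(ang) if ang is not None else (0.5, 0.5, 0.5)
        pos = tr.positions()
        ax.plot(pos[:, 0], pos[:, 1], color=color, lw=1.0)
    ax.plot(*spec.center, "wo", mec="k", ms=6)
    w, h = spec.field_size_um
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # image convention: y downward
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title("EB1 comet trajectories (colour = direction)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def profile_figure(
    profiles: Sequence[LineProfile],
    labels: Sequence[str],
    path: str | Path,
) -> None:
    """Overlaid line-scan profiles sharing one distance axis."""
    fig, ax = plt.subplots(figsize=(5, 3))
    for p, lbl in zip(profiles, labels):
        ax.plot(p.distances_um, p.values, label=lbl)
    ax.set_xlabel("distance along scan line (µm)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
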
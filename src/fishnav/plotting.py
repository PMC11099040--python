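"""Minimal trajectory plotting (diagnostics, not figure reproduction)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .arena import ArenaConfig, ModelTrajectory
from .trajectory import Trajectory

_LABEL_COLORS = {"PI": "tab:green", "APC": "tab:gray", "RR": "tab:orange", "RANDOM": "tab:purple"}


def plot_trajectories(
    trajectories: Iterable[Trajectory],
    config: ArenaConfig,
    labels: Mapping[str, str] | None = None,
    models: Iterable[ModelTrajectory] = (),
    out_path: str | Path | None = None,
):
    """Overhead view of trajectories coloured by label, with model paths.

    Returns the matplotlib figure; writes a PNG when ``out_path`` given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in trajectories:
        color = _LABEL_COLORS.get((labels or {}).get(tr.trial_id, ""), "0.6")
        ax.plot(tr.xy[:, 0], tr.xy[:, 1], color=color, lw=0.8, alpha=0.7)
        ax.plot(*tr.xy[0], marker="o", ms=3, color=color)
    for m in models:
        ax.plot(m.polyline[:, 0], m.polyline[:, 1], "k--", lw=1.5)
    ax.set_xlim(0, config.tank_side)
    ax.set_ylim(config.tank_side, 0)  # y grows downward (overhead camera)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
    return fig
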
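"""Trajectory plots: tracking overlap and segmented response overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; callers needing interactivity switch backends first

import matplotlib.pyplot as plt
import numpy as np

from .ct import residual_error_series
from .msg import segment_responses
from .session import CT, SessionLog


def plot_ct_trial(log: SessionLog, ax=None):
    """Target and paddle trajectories of a cyclic-tracking trial."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = log.samples["t_ms"].to_numpy() / 1000.0
    col = "target_x" if log.config.axis == "horizontal" else "target_y"
    ax.plot(t, log.samples[col], label="target", lw=1.5)
    ax.plot(t, log.samples["paddle_pos"], label="paddle", lw=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position (normalized)")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_ct_residuals(log: SessionLog, ax=None):
    """Per-sample residual tracking error over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2))
    t = log.samples["t_ms"].to_numpy() / 1000.0
    ax.plot(t, residual_error_series(log), lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("|error|")
    return ax


def plot_msg_overlays(log: SessionLog, ax=None):
    """Overlay of segmented game movement responses, colored by heading."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    responses = segment_responses(log)
    directions = sorted({r.direction for r in responses})
    cmap = plt.get_cmap("tab10")
    colors = {d: cmap(i % 10) for i, d in enumerate(directions)}
    seen = set()
    for r in responses:
        rel = (r.t_ms - r.t_ms[0]) / 1000.0
        label = r.direction if r.direction not in seen else None
        seen.add(r.direction)
        ax.plot(rel, r.trajectory - r.trajectory[0], color=colors[r.direction],
                alpha=0.6, lw=0.8, label=label)
    ax.set_xlabel("time from appearance (s)")
    ax.set_ylabel("displacement (normalized)")
    ax.legend(fontsize=8)
    return ax
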
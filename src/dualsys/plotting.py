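"""Figure helpers for the standard panels.

Thin matplotlib wrappers: rate/occupancy heatmaps, session latency curves,
stay-probability bar groups and the planning-versus-memory scatter.  Each
function draws on a provided (or fresh) Axes and returns it, so panels can
be composed freely.
"""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt

__all__ = [
    "plot_rate_map",
    "plot_latency_curves",
    "plot_stay_table",
    "plot_association",
]


def _ax(ax):
    return ax if ax is not None else plt.subplots()[1]


def plot_rate_map(values, grid_shape, ax=None, title=None, cmap="viridis"):
    """Heatmap of a per-state map (rates, occupancy or value) on the grid."""
    ax = _ax(ax)
    img = np.asarray(values, dtype=float).reshape(grid_shape).T
    m = ax.imshow(img, origin="lower", cmap=cmap)
    ax.figure.colorbar(m, ax=ax, shrink=0.8)
    ax.set_xlabel("x (cells)")
    ax.set_ylabel("y (cells)")
    if title:
        ax.set_title(title)
    return ax


def plot_latency_curves(result, ax=None, label=None, **kw):
    """Trial-1 (solid) and trial-4 (dashed) escape latencies per session."""
    ax = _ax(ax)
    sessions = np.arange(1, result.latencies.shape[1] + 1)
    ax.plot(sessions, result.trial_curve(1), "-o", label=f"{label or result.arm} trial 1", **kw)
    ax.plot(sessions, result.trial_curve(4), "--o", label=f"{label or result.arm} trial 4", **kw)
    ax.set_xlabel("session")
    ax.set_ylabel("escape latency (steps)")
    ax.legend()
    return ax


def plot_stay_table(table, ax=None, title=None):
    """Grouped bars: stay probability by previous reward x transition."""
    ax = _ax(ax)
    x = np.arange(2)
    width = 0.35
    ax.bar(x - width / 2, [table.rewarded_common, table.unrewarded_common], width, label="common")
    ax.bar(x + width / 2, [table.rewarded_rare, table.unrewarded_rare], width, label="rare")
    ax.set_xticks(x, ["rewarded", "unrewarded"])
    ax.set_ylim(0, 1)
    ax.set_ylabel("stay probability")
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_association(result, ax=None, **kw):
    """Per-agent MB index against place-memory strength with a fit line."""
    ax = _ax(ax)
    ok = np.isfinite(result.mb) & np.isfinite(result.memory)
    x, y = result.mb[ok], -result.memory[ok]
    ax.scatter(x, y, **kw)
    if len(x) >= 2:
        coef = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 20)
        ax.plot(xs, np.polyval(coef, xs), "-", alpha=0.7)
    ax.set_xlabel("model-based index")
    ax.set_ylabel("place-memory strength (-distance)")
    ax.set_title(f"{result.arm}: r = {result.r:.2f}, z = {result.z:.2f}")
    return ax
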
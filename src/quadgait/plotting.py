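"""Figure helpers for the standard analysis surfaces.

All functions take an optional matplotlib Axes and return it, so they
compose into panel layouts; nothing here touches global figure state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["circular_phase_plot", "poincare_plot", "stick_figure"]


def circular_phase_plot(phases, ax=None, color="tab:blue", label=None):
    """Phase fractions on a unit circle (0/1 at top, 0.5 at bottom).

    Each step is one point on the rim; the mean resultant vector is drawn
    from the centre (length = coupling strength).
    """
    import matplotlib.pyplot as plt

    phases = np.asarray(pd.Series(phases).dropna(), dtype=float)
    theta = 2 * np.pi * phases
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.scatter(theta, np.ones_like(theta), s=12, alpha=0.6, color=color,
               label=label)
    if len(theta):
        c, s = np.cos(theta).mean(), np.sin(theta).mean()
        r = np.hypot(c, s)
        ax.annotate("", xy=(np.arctan2(s, c), r), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color=color, lw=2))
    ax.set_yticklabels([])
    ax.set_xticks(np.linspace(0, 2 * np.pi, 4, endpoint=False))
    ax.set_xticklabels(["0/1", "0.25", "0.5", "0.75"])
    return ax


def poincare_plot(pairs: pd.DataFrame, ax=None, color="tab:blue", label=None):
    """Lag-1 scatter of successive phases (step n vs step n+1)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pairs.phase_n, pairs.phase_n1, s=12, alpha=0.6, color=color,
               label=label)
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls="--")
    ax.set_xlabel("phase, step n")
    ax.set_ylabel("phase, step n+1")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def stick_figure(markers: pd.DataFrame, every: int = 5, ax=None,
                 color="tab:blue"):
    """Sagittal stick figure: I-H-A-T chains drawn every `every` frames."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    wide = markers.pivot_table(index="frame", columns="marker",
                               values=["x_cm", "y_cm"])
    order = ["iliac_crest", "hip", "ankle", "toe"]
    for frame in wide.index[::every]:
        xs = [wide.loc[frame, ("x_cm", m)] for m in order]
        ys = [wide.loc[frame, ("y_cm", m)] for m in order]
        ax.plot(xs, ys, "-o", color=color, ms=2, lw=0.8, alpha=0.6)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    return ax
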
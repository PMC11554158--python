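"""Figure-style plots for runs: growth curves, X2 envelopes, C/N ratio,
cross-sections.  These views are diagnostic conveniences and are
non-normative: no analysis result depends on them.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis_io import TrajectoryRecord, cn_ratio, reference_curve
from .model_core import COLOR_NAMES, Population


def plot_growth_curves(
    runs: dict[str, Sequence[TrajectoryRecord]],
    T_CC: float | None = None,
    ax=None,
):
    """Semi-log N(t) for one or more runs, with the doubling-law reference."""
    if ax is None:
        _, ax = plt.subplots()
    for label, records in runs.items():
        t = np.array([r.t for r in records]) / 3600.0
        n = [r.N for r in records]
        ax.semilogy(t, n, label=label)
    if T_CC is not None and runs:
        records = next(iter(runs.values()))
        t = np.array([r.t for r in records])
        ax.semilogy(t / 3600.0, reference_curve(t, T_CC), "--",
                    label="doubling law", color="gray")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("number of cells")
    ax.legend()
    return ax


def plot_x2_envelope(records: Sequence[TrajectoryRecord], X_th: float, ax=None):
    """Max/mean/min nuclear YAP/TAZ over time against the arrest threshold."""
    if ax is None:
        _, ax = plt.subplots()
    t = np.array([r.t for r in records]) / 3600.0
    for attr, color in (("X2_max", "red"), ("X2_mean", "green"), ("X2_min", "blue")):
        ax.plot(t, [getattr(r, attr) for r in records], color=color, label=attr)
    ax.axhline(X_th, linestyle="--", color="black", label="X_th")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("nuclear YAP/TAZ (uM)")
    ax.legend()
    return ax


def plot_cn_ratio(
    normal: Sequence[TrajectoryRecord],
    cancer: Sequence[TrajectoryRecord],
    ax=None,
):
    """Cancer/normal mean nuclear YAP/TAZ ratio over time."""
    if ax is None:
        _, ax = plt.subplots()
    pts = cn_ratio(normal, cancer)
    ax.plot([t / 3600.0 for t, _ in pts], [v for _, v in pts])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("X2 mean ratio (cancer / normal)")
    return ax


def plot_cross_section(pop: Population, ax=None):
    """Cells intersecting the x = 0 plane (those with |x| < radius), drawn in
    the y-z plane with their in-plane circle radii and phase colours."""
    if ax is None:
        _, ax = plt.subplots()
    radius = pop.radius
    mask = np.abs(pop.r[:, 0]) < radius
    for i in np.nonzero(mask)[0]:
        in_plane = float(np.sqrt(radius[i] ** 2 - pop.r[i, 0] ** 2))
        circ = plt.Circle((pop.r[i, 1], pop.r[i, 2]), in_plane,
                          color=COLOR_NAMES[int(pop.color[i])], alpha=0.7)
        ax.add_patch(circ)
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.set_xlabel("y (um)")
    ax.set_ylabel("z (um)")
    return ax
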
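"""Optional matplotlib figures for sweep, surface and region results.

Simplex scatter uses a plain barycentric projection onto 2-D axes.  Plots
are conveniences for inspection; no analysis depends on them.
"""

from __future__ import annotations

import numpy as np

from .dynamics import SimplexClassification
from .experiments import RegionGrid, SweepResult


def _require_mpl():
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("matplotlib is required for plotting") from exc
    return plt


def band_plot(result: SweepResult, ax=None):
    """Mean line with shaded 95% band over the sweep grid."""
    plt = _require_mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    g = np.asarray(result.grid)
    ax.fill_between(g, result.lower, result.upper, alpha=0.25, lw=0)
    ax.plot(g, result.mean, "-", lw=1.5)
    ax.set_xlabel(result.sweep_var)
    ax.set_ylabel(result.outcome)
    return ax


def region_plot(grid: RegionGrid, ax=None):
    """Heatmap of mean male advantage over (x_cm, q_coal); favored cells dark."""
    plt = _require_mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(grid.favored.T, origin="lower", extent=(0, 1, 0, 1),
              cmap="Greys", vmin=0, vmax=1, aspect="auto")
    ax.set_xlabel("x_cm")
    ax.set_ylabel("q_coal")
    ax.set_title(f"r={grid.r_kin:g}, a={grid.a_assort:g}")
    return ax


def simplex_plot(cls: SimplexClassification, ax=None):
    """Barycentric scatter of favored strategies over the female simplex."""
    plt = _require_mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    # corners: CM left, OM right, IM top
    px = cls.y + 0.5 * cls.z
    py = (np.sqrt(3) / 2) * cls.z
    colors = {"CM": "0.4", "OM": "white", "IM": "tab:blue", "tie": "red"}
    for label in ("CM", "OM", "IM", "tie"):
        m = cls.labels == label
        if m.any():
            ax.scatter(px[m], py[m], s=12, c=colors[label], edgecolors="0.7",
                       linewidths=0.3, label=label)
    ax.plot([0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0], "k-", lw=1)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", fontsize=8)
    return ax
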
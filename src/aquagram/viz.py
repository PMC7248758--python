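"""Radar-chart rendering of aquagram results.

Twelve axes ordered C01 -> C12 clockwise from the top; per group a solid
line for the value, dashed for the upper and dotted for the lower 95%
confidence limit.  SVG output is deterministic (fixed hash salt, no
creation date) so rendered files can be compared byte-for-byte.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .results import AquagramResult

__all__ = ["render_aquagram"]


def render_aquagram(
    result: AquagramResult,
    out,
    title: str = "",
    color_cycle=None,
    radial_label: str | None = None,
    radial_limits: tuple[float, float] | None = None,
    mode: str | None = None,
) -> tuple[float, float]:
    """Write an aquagram radar chart as SVG or PNG (by file extension).

    ``radial_limits`` defaults to the data range padded by 10%.  For
    results carrying both absolute and delta rows, ``mode`` selects which
    to draw (default ``"absolute"``).  Returns the radial limits used.
    """
    table = result.table
    if "mode" in table.columns:
        table = table[table["mode"] == (mode or "absolute")]
    if table.empty:
        raise ValueError("result has no rows to render")
    groups = list(table["group"].unique())
    coords = list(table["coordinate"].unique())
    k = len(coords)
    # clockwise from top
    theta = np.pi / 2 - 2 * np.pi * np.arange(k + 1) / k

    with plt.rc_context({"svg.hashsalt": "aquagram"}):
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
        if color_cycle is not None:
            ax.set_prop_cycle(color=list(color_cycle))
        for g in groups:
            sub = table[table["group"] == g].set_index("coordinate").loc[coords]
            val = sub["value"].to_numpy()
            line, = ax.plot(theta, np.r_[val, val[:1]], "-", label=str(g))
            for col, style in (("ucl95", "--"), ("lcl95", ":")):
                v = sub[col].to_numpy()
                ax.plot(theta, np.r_[v, v[:1]], style, color=line.get_color(),
                        linewidth=0.8)
        ax.set_xticks(theta[:-1])
        ax.set_xticklabels(coords)
        if radial_limits is None:
            finite = table[["value", "lcl95", "ucl95"]].to_numpy()
            finite = finite[np.isfinite(finite)]
            lo, hi = float(finite.min()), float(finite.max())
            pad = 0.1 * (hi - lo) if hi > lo else 1.0
            radial_limits = (lo - pad, hi + pad)
        ax.set_ylim(*radial_limits)
        if radial_label is None:
            radial_label = "degC" if result.mode == "temperature" else "z-score"
        ax.set_title(title or f"Aquagram ({result.mode} mode, {radial_label})")
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
        fig.savefig(out, bbox_inches="tight", metadata={"Date": None}
                    if str(out).endswith(".svg") else None)
        plt.close(fig)
    return radial_limits
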
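"""Dot-and-range panels for subgroup benchmarks."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_subgroup_range(
    ranges: pd.DataFrame,
    title: str = "",
    path: Optional[Union[str, Path]] = None,
):
    """Median dot, interquartile band and min-max whisker per subgroup.

    ``ranges`` is the output of :func:`vaxineq.benchmark.subgroup_range`.
    Saves to ``path`` (format from the extension, e.g. .svg or .png) when
    given; returns the matplotlib figure either way.
    """
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(ranges) + 1.2))
    y = range(len(ranges))
    ax.barh(
        y,
        ranges["q3"] - ranges["q1"],
        left=ranges["q1"],
        height=0.55,
        color="0.85",
        zorder=1,
        label="interquartile range",
    )
    ax.hlines(y, ranges["min"], ranges["max"], color="0.5", lw=1, zorder=2)
    ax.plot(ranges["median"], y, "o", color="tab:blue", zorder=3, label="median")
    ax.set_yticks(list(y), ranges["subgroup_id"])
    ax.invert_yaxis()
    ax.set_xlabel("estimate (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
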
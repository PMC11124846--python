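"""Line-and-ribbon plots for experiment curves."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_curve(
    curve: pd.DataFrame,
    metric: str = "accuracy",
    x_label: Optional[str] = None,
    band: str = "sd",
    ax=None,
    out=None,
):
    """Plot mean metric vs x with a ±sd (or ±stderr) ribbon.

    Per-class rows of the metric are drawn as separate lines; the
    overall row (empty class) is drawn in black.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = curve[curve["metric"] == metric]
    for cls, grp in sub.groupby("class"):
        grp = grp.sort_values("x")
        label = cls if cls else metric
        color = "black" if not cls else None
        (line,) = ax.plot(grp["x"], grp["mean"], marker="o", ms=3, label=label, color=color)
        spread = grp[band].fillna(0.0)
        ax.fill_between(
            grp["x"], grp["mean"] - spread, grp["mean"] + spread,
            alpha=0.2, color=line.get_color(),
        )
    ax.set_xlabel(x_label or {"window_sweep": "smoothing window (s)",
                              "data_reduction": "proportion of data retained"}.get(
        curve["experiment"].iloc[0] if len(curve) else "", "x"))
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
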
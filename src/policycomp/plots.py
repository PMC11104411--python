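"""Static figures: trade-off panels per set size and learning curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def tradeoff_panels(points: pd.DataFrame, curves: dict, path) -> None:
    """One panel per set size: optimal frontier plus empirical points."""
    sizes = sorted(points["set_size"].unique())
    fig, axes = plt.subplots(1, len(sizes), figsize=(3.2 * len(sizes), 3.2),
                             sharey=True)
    if len(sizes) == 1:
        axes = [axes]
    for ax, n in zip(axes, sizes):
        curve = curves[int(n)]
        ax.plot(curve.complexities, curve.rewards, "k-", lw=1.5, label="optimal")
        for grp, sub in points[points["set_size"] == n].groupby("group"):
            ax.scatter(sub["complexity_nats"], sub["reward"], s=12, alpha=0.6,
                       label=grp)
        ax.set_title(f"set size {int(n)}")
        ax.set_xlabel("policy complexity (nats)")
    axes[0].set_ylabel("average reward")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def learning_curve_plot(curves: pd.DataFrame, path) -> None:
    """P(correct) by presentation index, one line per set size, per group."""
    groups = sorted(curves["group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(4.2 * len(groups), 3.4),
                             sharey=True)
    if len(groups) == 1:
        axes = [axes]
    for ax, grp in zip(axes, groups):
        sub = curves[curves["group"] == grp]
        for n, line in sub.groupby("set_size"):
            ax.plot(line["presentation"], line["p_correct"], marker="o", ms=3,
                    label=f"n={int(n)}")
        ax.axhline(1 / 3, color="gray", ls=":", lw=1)
        ax.set_title(grp)
        ax.set_xlabel("stimulus presentation")
    axes[0].set_ylabel("P(correct)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
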
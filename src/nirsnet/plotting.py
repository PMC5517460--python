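"""Summary line plots of stability / reliability against scanning duration."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends beforehand
import matplotlib.pyplot as plt


def plot_duration_curves(
    result,
    statistic: str = "stability_r_mean",
    table: str = "stability",
    out_path=None,
):
    """One panel per (method, mode): the chosen statistic vs duration for
    every metric in the sweep result.  Returns the figure."""
    df = getattr(result, table)
    sel = df[df.statistic == statistic]
    combos = sorted(set(zip(sel.method, sel["mode"])))
    fig, axes = plt.subplots(
        1, max(len(combos), 1), figsize=(4.5 * max(len(combos), 1), 3.5),
        squeeze=False)
    for ax, (method, mode) in zip(axes[0], combos):
        g = sel[(sel.method == method) & (sel["mode"] == mode)]
        for metric, gm in g.groupby("metric"):
            gm = gm.sort_values("duration_s")
            ax.plot(gm.duration_s, gm.value, marker="o", ms=3, label=metric)
        ax.set_xlabel("scanning duration (s)")
        ax.set_ylabel(statistic)
        ax.set_title(f"{method} / {mode}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
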
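"""Plot helpers for time-resolved bias/precision panels."""

from __future__ import annotations

from .timecourse import ClusterResult, TimecourseStat

BLOCK_COLORS = {"narrow": "tab:green", "wide": "tab:red"}


def plot_timecourse(
    stat: TimecourseStat,
    clusters: dict[str, ClusterResult] | None = None,
    contrasts: tuple[str, ...] = ("high", "low"),
):
    """Bias-ratio and direction-SD curves per contrast, narrow vs wide.

    Returns a matplotlib Figure with one column per contrast and two rows
    (direction-difference ratio on top, direction SD below).  Significant
    clusters, if given per contrast, are drawn as horizontal bars.
    """
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, len(contrasts), figsize=(4.5 * len(contrasts), 6),
                             sharex=True, squeeze=False)
    t = stat.time_ms
    for j, contrast in enumerate(contrasts):
        ax_bias, ax_sd = axes[0][j], axes[1][j]
        for block in ("wide", "narrow"):
            color = BLOCK_COLORS[block]
            rb = stat.ratio_bias.get((block, contrast))
            if rb is not None:
                ax_bias.plot(t, rb, color=color, label=f"{block} prior")
            sd = stat.sd.get((block, contrast))
            if sd is not None:
                ax_sd.plot(t, sd, color=color, label=f"{block} prior")
        ax_bias.axhline(1.0, color="0.6", lw=0.8, ls=":")
        ax_bias.set_title(f"{contrast} contrast")
        ax_bias.set_ylabel("direction difference ratio")
        ax_sd.set_ylabel("pursuit direction SD (deg)")
        ax_sd.set_xlabel("time from motion onset (ms)")
        if clusters and contrast in clusters:
            res = clusters[contrast]
            ymax = ax_sd.get_ylim()[1]
            for (a, b) in res.intervals:
                ax_sd.hlines(ymax * 0.98, a, b, color="k", lw=3)
        ax_bias.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
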
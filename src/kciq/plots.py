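"""Optional figures: through-focus curves, IQ box plots, envelope scatter."""

from __future__ import annotations

import numpy as np


def plot_median_curves(group_curves: dict, path=None):
    """Median (25th-75th IQR) through-focus curves, one panel per group.

    ``group_curves`` maps a panel label to a list of ThroughFocusCurve.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .throughfocus import median_curve

    fig, axes = plt.subplots(1, len(group_curves), sharey=True,
                             figsize=(4 * len(group_curves), 3.2))
    axes = np.atleast_1d(axes)
    for ax, (label, curves) in zip(axes, group_curves.items()):
        v, med, q25, q75 = median_curve(curves)
        ax.plot(v, med, "o-", color="k", ms=3)
        ax.plot(v, q25, "-", color="0.6", lw=0.8)
        ax.plot(v, q75, "-", color="0.6", lw=0.8)
        ax.set_title(label, fontsize=9)
        ax.set_xlabel("vergence (D, myopia positive)")
    axes[0].set_ylabel("logNS")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_iq_boxes(table, variables=("peak_iq", "best_focus_D", "dof_D"),
                  path=None):
    """Box plots of the IQ parameters per cohort-condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(table.groupby(["cohort", "condition"]).groups)
    fig, axes = plt.subplots(1, len(variables), figsize=(4 * len(variables), 3.2))
    for ax, var in zip(np.atleast_1d(axes), variables):
        data = [table[(table["cohort"] == c) & (table["condition"] == k)][var]
                for c, k in groups]
        ax.boxplot(data, tick_labels=[f"{c}\n{k}" for c, k in groups])
        ax.set_ylabel(var)
        ax.tick_params(axis="x", labelsize=7)
        if var == "best_focus_D":
            ax.axhline(0.0, color="0.7", lw=0.8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_envelope(table, envelope, path=None):
    """Best focus and DOF against peak IQ, with the 10th/90th focus envelope."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax1.plot(table["peak_iq"], table["best_focus_D"], "ko", ms=3)
    ax1.axhline(0.0, color="0.6", lw=0.8)
    if envelope is not None:
        ax1.plot(envelope["x_center"], envelope["q_low"], "k--", lw=0.8)
        ax1.plot(envelope["x_center"], envelope["q_high"], "k--", lw=0.8)
    ax1.set_xlabel("peak IQ (logNS)")
    ax1.set_ylabel("best focus (D)")
    ax2.plot(table["peak_iq"], table["dof_D"], "ko", ms=3)
    ax2.set_xlabel("peak IQ (logNS)")
    ax2.set_ylabel("DOF (D)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
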
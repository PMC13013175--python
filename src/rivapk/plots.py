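"""Basic diagnostic figures: goodness-of-fit panels and the pcVPC plot.

Deliberately minimal — enough to eyeball a fit; publication styling is out
of scope.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_gof", "plot_vpc", "plot_exposure_boxes"]


def plot_gof(gof, figsize=(9, 8)):
    """Four-panel goodness-of-fit figure from :func:`rivapk.gof_table`
    output: DV vs IPRED, DV vs PRED, CWRES vs time, CWRES vs PRED."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=figsize)
    for ax, x, xlab in ((axes[0, 0], gof["IPRED"], "individual prediction (µg/L)"),
                        (axes[0, 1], gof["PRED"], "population prediction (µg/L)")):
        ax.plot(x, gof["DV"], "o", ms=4, alpha=0.6)
        lim = [0.0, max(float(np.max(x)), float(gof["DV"].max())) * 1.05]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel("observed (µg/L)")
    for ax, x, xlab in ((axes[1, 0], gof["TIME"], "time (h)"),
                        (axes[1, 1], gof["PRED"], "population prediction (µg/L)")):
        ax.plot(x, gof["CWRES"], "o", ms=4, alpha=0.6)
        ax.axhline(0.0, color="k", lw=1)
        for y in (-5, 5):
            ax.axhline(y, color="k", lw=0.8, ls="--")
        ax.set_xlabel(xlab)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    return fig


def plot_vpc(vpc, figsize=(7, 5)):
    """Prediction-corrected VPC: observed percentiles per bin with the
    simulated 90% confidence bands."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=figsize)
    colors = {5.0: "tab:purple", 50.0: "tab:red", 95.0: "tab:purple"}
    for p in vpc.percentiles:
        sub = vpc.table[vpc.table["percentile"] == p].sort_values("bin")
        ax.fill_between(sub["bin"], sub["band_lo"], sub["band_hi"],
                        alpha=0.25, color=colors.get(p, "gray"))
        ax.plot(sub["bin"], sub["observed"], "o-", color=colors.get(p, "gray"),
                label=f"observed P{p:g}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (µg/L)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_exposure_boxes(results, thresholds, figsize=(9, 4)):
    """Box plots of simulated AUC and Cmax per dose with the safety limits,
    from a list of :class:`rivapk.AttainmentResult`."""
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=figsize)
    doses = [f"{r.dose:g} mg" for r in results]
    ax1.boxplot([r.exposures["auc_ss_24"] for r in results], tick_labels=doses)
    ax1.axhline(thresholds.auc_max, color="k", ls="--")
    ax1.set_ylabel("AUC over one day at steady state (mg·h/L)")
    ax2.boxplot([r.exposures["cmax_ss"] for r in results], tick_labels=doses)
    ax2.axhline(thresholds.cmax_max, color="k", ls="--")
    ax2.set_ylabel("steady-state peak (µg/L)")
    fig.tight_layout()
    return fig
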
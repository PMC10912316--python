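"""Figure hooks: fitted time-courses with credible envelopes and the
source-resolved influx decomposition."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_SERIES = (("control", "GCB_CARpos", "tab:red", "CAR+ GCB (control)"),
           ("control", "MZB_CARpos", "tab:red", "CAR+ MZB (control)"),
           ("n2ko", "MZB_CARpos", "tab:blue", "CAR+ MZB (N2KO)"))


def plot_trajectory_fit(fit, data, path, times=None):
    """Three panels: per-mouse counts (dots), posterior-median curve and 95%
    credible envelope for each fitted CAR+ series."""
    if times is None:
        times = np.linspace(4.0, float(data.to_frame()["day"].max()), 60)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
    for ax, (group, pop, color, label) in zip(axes, _SERIES):
        env = fit.trajectory_envelope(times, group=group, population=pop)
        obs = data.observations(group, pop)
        ax.fill_between(env["time"], env["ci_low"], env["ci_high"],
                        color=color, alpha=0.2, lw=0)
        ax.plot(env["time"], env["median"], color=color)
        ax.plot(obs["day"], obs["count"], "o", ms=4, color=color, alpha=0.6)
        ax.set_yscale("log")
        ax.set_title(label, fontsize=10)
        ax.set_xlabel("days post-immunization")
    axes[0].set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_influx_decomposition(decomp, path):
    """Daily influx into the CAR+ MZB pool by source, % of pool per day."""
    s = decomp.summary
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.4), sharex=True)
    for ax, prefix, title in ((axes[0], "pct_carneg", "from CAR- MZB activation"),
                              (axes[1], "pct_fob", "from FoB differentiation")):
        ax.fill_between(s["time"], s[f"{prefix}_lo"], s[f"{prefix}_hi"],
                        alpha=0.25, lw=0)
        ax.plot(s["time"], s[f"{prefix}_mean"])
        ax.set_title(title, fontsize=10)
        ax.set_xlabel("days post-immunization")
    axes[0].set_ylabel("influx (% of CAR+ MZB pool / day)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
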
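"""Minimal plotting helpers for grid results and planning distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_power_rmse(results: pd.DataFrame, out_path: str) -> str:
    """Power and RMSE vs confounding strength, one line per strategy."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for strategy, grp in results.groupby("strategy"):
        grp = grp.sort_values("rho")
        axes[0].plot(grp["rho"], grp["adjust_rate"], marker="o", label=strategy)
        axes[1].plot(grp["rho"], grp["rmse"], marker="o", label=strategy)
    axes[0].set_xlabel(r"exposure-confounder correlation $\rho$")
    axes[0].set_ylabel("adjust rate")
    axes[1].set_xlabel(r"exposure-confounder correlation $\rho$")
    axes[1].set_ylabel("RMSE of final effect")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_adjusted_rr_hist(summary: dict, out_path: str, unadjusted_rr: float = None) -> str:
    """Histogram of the adjusted risk ratio at one noise-to-signal ratio."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = summary["hist_edges"]
    ax.stairs(summary["hist_counts"], edges, fill=True, alpha=0.7)
    ax.axvline(1.0, color="k", lw=1, label="null RR = 1")
    if unadjusted_rr is not None:
        ax.axvline(unadjusted_rr, color="r", lw=1, ls="--", label="unadjusted RR")
    ax.set_xlabel("adjusted RR")
    ax.set_ylabel("simulations")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
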
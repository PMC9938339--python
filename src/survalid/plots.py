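"""Minimal plotting: calibration plot and risk-group survival curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_calibration", "plot_risk_group_curves"]


def plot_calibration(decile_table: pd.DataFrame, path, title: str = "Calibration") -> None:
    """Observed vs mean predicted risk per bin with the 45-degree ideal line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(decile_table["mean_predicted"].max(), decile_table["observed"].max()) * 1.1
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=1, label="ideal")
    ax.plot(decile_table["mean_predicted"], decile_table["observed"], "o-", c="tab:blue")
    ax.set_xlabel("Mean predicted risk")
    ax.set_ylabel("Observed risk at horizon")
    ax.set_title(title)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_risk_group_curves(curves: dict, path, horizon: float = 10.0) -> None:
    """Kaplan-Meier survivor curves of the prognostic-index risk groups."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in curves.items():
        t = [0.0] + list(curve.event_times)
        s = [1.0] + list(curve.survival)
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("Years")
    ax.set_ylabel("Survival free of outcome")
    ax.set_xlim(0, horizon)
    ax.set_ylim(0, 1.02)
    ax.legend(title="Risk group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
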
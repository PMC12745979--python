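"""Minimal plotting mirrors of the report figures (boxplots, curve bands)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_reproduction_boxplots(
    groups: dict[str, list[float]], path: str | Path, ylabel: str = "n_uq_repro"
) -> None:
    """Boxplots (quartiles, 1.5-IQR whiskers) of reproduction counts per group."""
    fig, ax = plt.subplots(figsize=(1.2 * max(len(groups), 2) + 1, 3.2))
    labels = list(groups)
    ax.boxplot([groups[k] for k in labels], tick_labels=labels, whis=1.5)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_randomization_curves(
    curves: dict[str, pd.DataFrame], path: str | Path
) -> None:
    """Mean lines with ±1 sd shaded bands vs number of randomized residues."""
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    for kind, frame in curves.items():
        x = frame["n_residues_randomized"]
        mean, sd = frame["mean"], frame["sd"].fillna(0.0)
        ax.plot(x, mean, label=kind)
        ax.fill_between(x, mean - sd, mean + sd, alpha=0.25)
    ax.set_xlabel("n_residues randomized")
    ax.set_ylabel("n_uq_repro compounds")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
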
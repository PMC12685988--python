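"""Cohort figures: stress quartile band, CS/CE boxplots, CT scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def quartile_band_plot(table: pd.DataFrame, path: str | Path) -> None:
    """Log-scale band plot of the per-strain stress quartiles."""
    strains = [float(c) for c in table.columns]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        strains, table.loc["minimum"], table.loc["maximum"], alpha=0.2, label="min-max"
    )
    ax.fill_between(
        strains, table.loc["p25"], table.loc["p75"], alpha=0.4, label="IQR"
    )
    ax.plot(strains, table.loc["median"], color="k", label="median")
    ax.set_yscale("log")
    ax.set_xlabel("strain")
    ax.set_ylabel("stress [MPa]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def stiffness_boxplots(results: pd.DataFrame, path: str | Path) -> None:
    """Side-by-side boxplots of the CS and CE parameters."""
    cs_cols = sorted(
        (c for c in results.columns if c.startswith("CS") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    ce_cols = sorted(
        (c for c in results.columns if c.startswith("CE") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, cols, label in ((axes[0], cs_cols, "CS [MPa]"), (axes[1], ce_cols, "CE [J/cm$^3$]")):
        data = [results[c].dropna() for c in cols]
        ax.boxplot(data, tick_labels=cols)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ct_scatter(results: pd.DataFrame, path: str | Path) -> None:
    """CT density vs low-strain stiffness (CS10, CE20)."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, col in ((axes[0], "CS10"), (axes[1], "CE20")):
        if col in results:
            ax.scatter(results["ct_hu"], results[col], s=12, alpha=0.7)
            ax.set_yscale("log")
            ax.set_xlabel("mean CT number [HU]")
            ax.set_ylabel(col)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
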
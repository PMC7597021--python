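"""Matplotlib figures for the standard outputs (trajectories, Manhattan
scans, bioassay mortality bars)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

CLASS_COLORS = {"1a": "#e08214", "1b": "#c51b8a", "2": "#2b6cb3"}


def trajectory_plot(table: pd.DataFrame, path: str | Path,
                    title: str = "") -> None:
    """Mean haplotype-class frequency per generation with SEM bars."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cls in ("1a", "1b", "2"):
        grp = table.groupby("generation")[f"f_{cls}"]
        mean, sem = grp.mean(), grp.sem()
        ax.errorbar(mean.index, mean, yerr=sem, marker="o", capsize=3,
                    label=f"class {cls}", color=CLASS_COLORS[cls])
    ax.set_xlabel("generation")
    ax.set_ylabel("haplotype class frequency")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def manhattan_plot(scan: pd.DataFrame, path: str | Path,
                   marker_positions=None, resistance_positions=None,
                   title: str = "") -> None:
    """-log10 p along the window; class-1 markers in black, resistance
    sites highlighted in orange."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ok = scan["pvalue"].notna()
    ax.scatter(scan.loc[ok, "pos"] / 1e6, scan.loc[ok, "neglog10_p"],
               s=6, color="lightgray", label="SNPs")
    for positions, color, label in (
            (marker_positions, "black", "class-1 markers"),
            (resistance_positions, "#e08214", "resistance sites")):
        if positions is not None:
            sel = ok & scan["pos"].isin(list(positions))
            ax.scatter(scan.loc[sel, "pos"] / 1e6,
                       scan.loc[sel, "neglog10_p"], s=14, color=color,
                       label=label)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mortality_bar_plot(summary: pd.DataFrame, path: str | Path) -> None:
    """Average mortality with SEM bars per population and insecticide."""
    insecticides = summary["insecticide"].unique()
    fig, axes = plt.subplots(1, len(insecticides),
                             figsize=(3.5 * len(insecticides), 3.5),
                             squeeze=False)
    for ax, ins in zip(axes[0], insecticides):
        sub = summary[summary["insecticide"] == ins]
        x = np.arange(len(sub))
        ax.bar(x, sub["mean_mortality"], yerr=sub["sem"], capsize=3,
               color="#777777")
        ax.set_xticks(x, sub["population"], rotation=45, ha="right")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("mortality (24 h)")
        ax.set_title(ins)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
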
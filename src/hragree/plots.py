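"""Deterministic figures: phase boxplots and the Bland-Altman plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io_align import MERGED_PHASES  # noqa: E402

__all__ = ["phase_boxplot", "bland_altman_plot"]


def phase_boxplot(paired: pd.DataFrame, path, ref_label: str = "reference",
                  test_label: str = "test") -> Path:
    """Side-by-side bpm boxplots per phase for the two devices."""
    phases = [p for p in MERGED_PHASES if p in set(paired["phase"])]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    width = 0.35
    for off, col, label, color in ((-width / 2, "hr_ref", ref_label, "#4477aa"),
                                   (width / 2, "hr_test", test_label, "#ee6677")):
        data = [paired.loc[paired["phase"] == p, col].to_numpy() for p in phases]
        bp = ax.boxplot(data, positions=np.arange(len(phases)) + off,
                        widths=width * 0.9, patch_artist=True,
                        medianprops={"color": "black"})
        for box in bp["boxes"]:
            box.set_facecolor(color)
        ax.plot([], [], color=color, label=label, linewidth=6)
    ax.set_xticks(np.arange(len(phases)))
    ax.set_xticklabels(phases)
    ax.set_ylabel("heart rate (bpm)")
    ax.set_xlabel("experimental phase")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return path


def bland_altman_plot(paired: pd.DataFrame, report, path) -> Path:
    """Mean-vs-difference scatter with bias and limits of agreement.

    Bias and LoA are solid lines; their bootstrap CIs, when present on the
    report, are dashed.
    """
    mean_hr = (paired["hr_ref"] + paired["hr_test"]) / 2.0
    diff = paired["diff"]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(mean_hr, diff, s=8, alpha=0.4, color="#4477aa",
               edgecolors="none")
    for y, style in ((report.bias, "-"), (report.loa_lower, "-"),
                     (report.loa_upper, "-")):
        ax.axhline(y, color="black", linestyle=style, linewidth=1.2)
    for ci in (report.bias_ci, report.loa_lower_ci, report.loa_upper_ci):
        if ci is not None:
            for y in ci:
                ax.axhline(y, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xlabel("mean of devices (bpm)")
    ax.set_ylabel("difference, test - reference (bpm)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return path
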
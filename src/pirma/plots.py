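"""Frequency-vs-month bar charts with binomial error bars.

Figures are always rendered from the tabular artifacts (panel summaries),
never recomputed, so plots cannot disagree with tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .estimation import binomial_se

__all__ = ["render_error_bar_plot"]


def _pane(ax, table: pd.DataFrame, group_col: str | None, title: str) -> None:
    months = sorted(table["month"].unique())
    groups = sorted(table[group_col].unique()) if group_col else ["All"]
    width = 0.8 / max(len(groups), 1)
    cmap = plt.get_cmap("tab10")
    for gi, group in enumerate(groups):
        sub = (
            table if group_col is None else table[table[group_col] == group]
        )
        xs, heights, errs, ns = [], [], [], []
        for mi, m in enumerate(months):
            row = sub[sub["month"] == m]
            if row.empty:
                continue
            n = int(row["n"].sum())
            pos = int(row["positives"].sum())
            p = pos / n
            xs.append(mi + (gi - (len(groups) - 1) / 2) * width)
            heights.append(p)
            errs.append(binomial_se(p, n))
            ns.append(n)
        bars = ax.bar(
            xs, heights, width=width * 0.9, yerr=errs, capsize=2,
            color=cmap(gi), label=str(group),
        )
        for x, h, e, n in zip(xs, heights, errs, ns):
            ax.annotate(
                str(n), (x, h + e), ha="center", va="bottom", fontsize=6,
                rotation=90,
            )
    ax.set_xticks(range(len(months)))
    ax.set_xticklabels([str(m) for m in months])
    ax.set_ylabel("frequency")
    ax.set_title(title, fontsize=9)
    if group_col:
        ax.legend(fontsize=7)


def render_error_bar_plot(
    frequencies: pd.DataFrame,
    path: str | Path,
    title: str = "Observed worsening frequency",
) -> Path:
    """Render stacked panes (All / by line / by drug) of frequencies.

    ``frequencies`` needs columns ``month``, ``n``, ``positives`` and
    optionally ``treatment_line`` / ``drug`` for the grouped panes.  Bar
    heights are the raw proportions; error bars the binomial standard
    errors; the per-bar annotation is the number of observations.
    """
    if frequencies.empty:
        raise ValueError("no frequencies to plot")
    panes: list[str | None] = [None]
    for col in ("treatment_line", "drug"):
        if col in frequencies.columns:
            panes.append(col)
    fig, axes = plt.subplots(
        len(panes), 1, figsize=(7, 2.6 * len(panes)), squeeze=False
    )
    for ax, col in zip(axes[:, 0], panes):
        _pane(ax, frequencies, col, title if col is None else f"by {col}")
    axes[-1, 0].set_xlabel("months since prescription start")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
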
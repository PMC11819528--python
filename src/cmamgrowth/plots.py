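"""Figure exports: weekly-curve panels and odds-ratio forest plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

GROUP_COLORS = {
    "recovered": "#2b8cbe",
    "high_growth_nr": "#e6550d",
    "low_growth_nr": "#756bb1",
}
GROUP_LABELS = {
    "recovered": "Recovered",
    "high_growth_nr": "High growth NR",
    "low_growth_nr": "Low growth NR",
}


def plot_weekly_curves(curves: dict[str, pd.DataFrame], path) -> Path:
    """Panel of modelled weekly means (one panel per outcome) with
    pointwise 95% bands, one curve per response category."""
    path = Path(path)
    n = len(curves)
    ncols = 2 if n > 1 else 1
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(5.5 * ncols, 3.8 * nrows),
                             squeeze=False)
    for ax, (outcome, df) in zip(axes.ravel(), curves.items()):
        for group, sub in df.groupby("group"):
            color = GROUP_COLORS.get(group, "grey")
            ax.plot(sub["week"], sub["mean"], color=color,
                    label=GROUP_LABELS.get(group, group))
            ax.fill_between(sub["week"], sub["ci_low"], sub["ci_high"],
                            color=color, alpha=0.2, linewidth=0)
        ax.set_xlabel("weeks since admission")
        ax.set_ylabel(outcome)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes[0, 0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def forest_plot(odds_ratios: pd.DataFrame, path) -> Path:
    """Forest plot of ORs with 95% CIs, one row per term, panelled by
    outcome contrast (reference: recovered)."""
    path = Path(path)
    outcomes = list(odds_ratios["outcome"].unique())
    fig, axes = plt.subplots(1, len(outcomes),
                             figsize=(4.5 * len(outcomes), 0.35 * odds_ratios["term"].nunique() + 2),
                             sharey=True, squeeze=False)
    terms = list(odds_ratios["term"].unique())
    ypos = {t: i for i, t in enumerate(terms)}
    for ax, outcome in zip(axes.ravel(), outcomes):
        sub = odds_ratios[odds_ratios["outcome"] == outcome]
        y = [ypos[t] for t in sub["term"]]
        finite = np.isfinite(sub["OR"]) & np.isfinite(sub["ci_high"])
        ax.errorbar(
            sub.loc[finite, "OR"], np.array(y)[finite.to_numpy()],
            xerr=[
                sub.loc[finite, "OR"] - sub.loc[finite, "ci_low"],
                sub.loc[finite, "ci_high"] - sub.loc[finite, "OR"],
            ],
            fmt="o", color=GROUP_COLORS.get(outcome, "black"), capsize=2,
        )
        ax.axvline(1.0, color="grey", linestyle="--", linewidth=0.8)
        ax.set_xscale("log")
        ax.set_title(GROUP_LABELS.get(outcome, outcome), fontsize=10)
        ax.set_xlabel("odds ratio vs recovered (log scale)")
    axes[0, 0].set_yticks(list(ypos.values()), list(ypos.keys()), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
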
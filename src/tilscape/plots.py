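"""Matplotlib output: Kaplan-Meier curves and hazard-ratio forest plots."""

from __future__ import annotations

from typing import Dict

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def km_plot(curves: Dict[str, object], path, title: str = "") -> None:
    """Plot the low/high product-limit curves from survival.km_curves."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name in ("low", "high"):
        sf = curves[name]
        ax.step(sf["time"], sf["survival"], where="post", label=name)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    p = curves.get("logrank_p")
    label = f"{title}  (log-rank p = {p:.3g})" if p is not None else title
    ax.set_title(label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest_plot(results: pd.DataFrame, path, title: str = "hazard ratios") -> None:
    """Forest plot of hazard ratios with 95% CIs, one row per result line."""
    df = results.dropna(subset=["hazard_ratio"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no fitted results to plot")
    labels = [
        f"{r.measure} [{r.endpoint}/{r.model}/{r.measure_scale}/{r.map_scale}]"
        for r in df.itertuples()
    ]
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(df) + 1.5))
    ax.errorbar(
        df["hazard_ratio"],
        y,
        xerr=[
            (df["hazard_ratio"] - df["ci_low"]).clip(lower=0),
            (df["ci_high"] - df["hazard_ratio"]).clip(lower=0),
        ],
        fmt="o",
        markersize=3,
        capsize=2,
        lw=1,
    )
    ax.axvline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (log scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
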
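"""Heatmap and predicted-vs-observed plots for study reports."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_heatmap(scores: pd.DataFrame, annotations: pd.DataFrame | None = None,
                 title: str = "Normalized performance (0 = worst, 1 = best)"):
    """White-to-blue heatmap of normalised scores, one row per biomarker."""
    fig, ax = plt.subplots(
        figsize=(1.4 * scores.shape[1] + 2, 0.5 * scores.shape[0] + 1.5)
    )
    im = ax.imshow(scores.to_numpy(float), cmap="Blues", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(scores.shape[1]), scores.columns, rotation=30,
                  ha="right")
    ax.set_yticks(range(scores.shape[0]), scores.index)
    ann = annotations if annotations is not None else scores
    for i in range(scores.shape[0]):
        for j in range(scores.shape[1]):
            v = ann.iloc[i, j]
            if pd.notna(v):
                dark = scores.iloc[i, j] > 0.6
                ax.text(j, i, f"{v:.3g}", ha="center", va="center",
                        fontsize=8, color="white" if dark else "black")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig


def plot_predicted_observed(fit, title: str = "Predicted vs observed"):
    """Model-predicted versus observed log-biomarker values with R^2."""
    obs = np.log(fit.model.series["value"].to_numpy(float))
    pred = fit.fittedvalues
    r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pred, obs, s=5, alpha=0.4)
    lims = [min(pred.min(), obs.min()), max(pred.max(), obs.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("predicted log(biomarker)")
    ax.set_ylabel("observed log(biomarker)")
    ax.set_title(title)
    ax.text(0.97, 0.03, f"$R^2$ = {r2:.3f}", transform=ax.transAxes,
            ha="right", va="bottom")
    fig.tight_layout()
    return fig
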
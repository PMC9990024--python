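"""Figure-style plots: KM step curves, rate bars with SE, logistic curve."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .escape import EscapeResults, predict_escape_probability  # noqa: E402
from .competitiveness import CompetitivenessResults  # noqa: E402
from .survival import SurvivalResults  # noqa: E402

__all__ = ["plot_km", "plot_escape_rates", "plot_escape_glm", "plot_hatch",
           "plot_fried", "save"]


def save(fig: plt.Figure, path: str | Path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_km(results: SurvivalResults) -> plt.Figure:
    """Kaplan-Meier step curves per treatment, mean survival in the legend."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for treatment, curve in results.curves.items():
        x = np.concatenate([[0.0], curve.event_times])
        y = np.concatenate([[1.0], curve.survival])
        letter = results.letters.get(treatment, "")
        ax.step(
            x, y, where="post",
            label=f"{treatment} (mean {curve.mean_survival:.0f} d) {letter}",
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return fig


def plot_escape_rates(results: EscapeResults) -> plt.Figure:
    """Mean escape rate per treatment with SE bars and letters."""
    fig, ax = plt.subplots(figsize=(7, 4))
    rates = results.rates
    x = np.arange(len(rates))
    pct = 100 * rates["rate_mean"].to_numpy()
    err = 100 * rates["rate_se"].to_numpy()
    colors = [
        "0.6" if t.startswith("C_") else "C0" for t in rates["treatment"]
    ]
    ax.bar(x, pct, yerr=np.nan_to_num(err), color=colors, capsize=3)
    for xi, p, e, t in zip(x, pct, err, rates["treatment"]):
        ax.text(xi, p + (e if np.isfinite(e) else 0) + 0.8,
                results.letters.get(t, ""), ha="center", fontsize=9)
    ax.set_xticks(x, rates["treatment"], rotation=30)
    ax.set_ylabel("escape rate (%)")
    return fig


def plot_escape_glm(results: EscapeResults) -> plt.Figure:
    """Fitted logistic escape-probability curve with replicate rates."""
    fig, ax = plt.subplots(figsize=(6, 4))
    data = results.model.data
    sub = data[data["second_chill_min"].notna() & (data["second_chill_min"] > 0)]
    ax.scatter(
        sub["second_chill_min"], sub["n_escaped"] / sub["n_loaded"],
        s=15, alpha=0.5, label="replicates",
    )
    grid = np.linspace(0, 110, 200)
    ax.plot(
        grid,
        [predict_escape_probability(results.glm, d) for d in grid],
        "k-", label="binomial GLM",
    )
    ax.set_xlabel("second chill duration (min)")
    ax.set_ylabel("escape probability")
    ax.legend(frameon=False)
    return fig


def plot_hatch(results: CompetitivenessResults) -> plt.Figure:
    """Per-arm hatch rate with cage-level SE bars."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = results.hatch_table
    x = np.arange(len(t))
    ax.bar(x, 100 * t["hatch_pooled"], yerr=100 * np.nan_to_num(t["hatch_cage_se"]),
           capsize=3, color="C2")
    ax.set_xticks(x, t["arm"])
    ax.set_ylabel("egg hatch rate (%)")
    return fig


def plot_fried(results: CompetitivenessResults) -> plt.Figure:
    """Competitiveness index and induced sterility per arm, with letters."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    arms = list(results.fried)
    x = np.arange(len(arms))
    c = [results.fried[a].C_point for a in arms]
    c_se = [results.fried[a].C_se for a in arms]
    is_ = [results.fried[a].IS_point for a in arms]
    is_se = [results.fried[a].IS_se for a in arms]
    axes[0].bar(x, c, yerr=c_se, capsize=3, color="C0")
    axes[0].set_xticks(x, arms, rotation=20)
    axes[0].set_ylabel("competitiveness index C")
    axes[1].bar(x, is_, yerr=is_se, capsize=3, color="C1")
    axes[1].set_xticks(x, arms, rotation=20)
    axes[1].set_ylabel("induced sterility (%)")
    for ax, vals, errs, lett in (
        (axes[0], c, c_se, results.letters_C),
        (axes[1], is_, is_se, results.letters_IS),
    ):
        for xi, v, e, arm in zip(x, vals, errs, arms):
            ax.text(xi, v + e + 0.02 * max(abs(min(vals)), abs(max(vals)), 1),
                    lett.get(arm, ""), ha="center", fontsize=9)
    fig.tight_layout()
    return fig
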
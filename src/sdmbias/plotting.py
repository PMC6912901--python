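"""Quick-look plots for experiment results (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiment import ExperimentResult

__all__ = ["plot_parameter_estimates", "plot_sex_ratios"]


def plot_parameter_estimates(result: ExperimentResult, model: str = "female", path=None):
    """Boxplots of replicate coefficient estimates per design/correction,
    with the true value as a horizontal reference line."""
    sub = result.fits[result.fits["model"] == model].dropna(subset=["est_slope"])
    truth = result.female if model == "female" else result.male
    covs = list(truth.slopes)
    scenarios = sorted(set(zip(sub["design"], sub["correction"])))
    fig, axes = plt.subplots(1, len(covs), figsize=(4 * len(covs), 4), sharey=False)
    for ax, cov in zip(axes, covs):
        data = [sub[(sub["design"] == d) & (sub["correction"] == c)][f"est_{cov}"].to_numpy()
                for d, c in scenarios]
        ax.boxplot(data, tick_labels=[f"{d[:4]}\n{c[:4]}" for d, c in scenarios])
        ax.axhline(truth.slopes[cov], color="red", lw=1)
        ax.set_title(cov)
    fig.suptitle(f"Coefficient estimates, {model} model")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_sex_ratios(result: ExperimentResult, path=None):
    """Boxplots of sex-ratio estimates per design/method with the target line."""
    sub = result.ratios[result.ratios["method"] != "truth"].dropna(subset=["ratio"])
    scenarios = sorted(set(zip(sub["design"], sub["method"])))
    fig, ax = plt.subplots(figsize=(1.2 * len(scenarios) + 2, 4))
    data = [sub[(sub["design"] == d) & (sub["method"] == m)]["ratio"].to_numpy()
            for d, m in scenarios]
    ax.boxplot(data, tick_labels=[f"{d[:4]}\n{m.removeprefix('model-')}" for d, m in scenarios])
    ax.axhline(result.true_ratio, color="red", lw=1)
    ax.set_ylabel("proportion of females")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
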
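"""Minimal figures: bootstrap r distributions and permutation-null histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_bootstrap_distributions(result, path: str | Path) -> None:
    """Histogram of per-iteration test r's over the pooled permutation null."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.null_draws, bins=40, alpha=0.6, density=True,
            label="permutation null", color="grey")
    ax.hist(result.per_iteration_r, bins=40, alpha=0.6, density=True,
            label="bootstrap models", color="steelblue")
    ax.axvline(result.mean_r, color="navy", linestyle=":",
               label=f"mean r = {result.mean_r:.2f}")
    ax.set_xlabel("test-set Pearson r")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_null_histogram(observed: float, null_draws, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(null_draws, bins=40, color="grey", alpha=0.8)
    ax.axvline(observed, color="navy", linestyle=":",
               label=f"observed = {observed:.2f}")
    ax.set_xlabel("null statistic")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
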
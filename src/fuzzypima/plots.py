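"""Optional plotting of class histograms and membership functions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fuzzy import FuzzyClassifierModel, FuzzyHistogram, MembershipFunction

__all__ = ["plot_histograms", "plot_membership_functions", "save_model_plots"]


def plot_histograms(model: FuzzyClassifierModel, ax=None):
    """Step plot of both class fuzzy histograms on the projection axis."""
    if ax is None:
        _, ax = plt.subplots()
    for hist, label, color in (
        (model.hist_healthy, "healthy (class 0)", "tab:blue"),
        (model.hist_sick, "sick (class 1)", "tab:red"),
    ):
        ax.stairs(hist.memberships, hist.bin_edges, label=label, color=color)
    ax.set_xlabel("projection axis z")
    ax.set_ylabel("membership")
    ax.set_title(f"Classifier {model.classifier_id}: fuzzy histograms")
    ax.legend()
    return ax


def plot_membership_functions(model: FuzzyClassifierModel, ax=None):
    """Aggregate healthy/sick membership functions of a fitted classifier."""
    if ax is None:
        _, ax = plt.subplots()
    lo = min(model.mf_healthy.z[0], model.mf_sick.z[0])
    hi = max(model.mf_healthy.z[-1], model.mf_sick.z[-1])
    grid = np.linspace(lo, hi, 512)
    ax.plot(grid, model.mf_healthy(grid), label="healthy aggregate", color="tab:blue")
    ax.plot(grid, model.mf_sick(grid), label="sick aggregate", color="tab:red")
    ax.set_xlabel("projection axis z")
    ax.set_ylabel("membership")
    ax.set_title(f"Classifier {model.classifier_id}: membership functions")
    ax.legend()
    return ax


def save_model_plots(model: FuzzyClassifierModel, outdir: str | Path) -> list[Path]:
    """Write histogram and membership-function figures as PNGs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, plotter in (
        ("histograms", plot_histograms),
        ("membership_functions", plot_membership_functions),
    ):
        fig, ax = plt.subplots(figsize=(7, 4))
        plotter(model, ax)
        path = outdir / f"classifier{model.classifier_id}_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
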
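"""Optional raster and population-PSTH figures (matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .binning import AlignedTrials
from .modulation import PopulationProfile

__all__ = ["plot_raster", "plot_population_profile"]


def plot_raster(aligned: AlignedTrials, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(6, 3))
    for i, rel in enumerate(aligned.rel_times):
        ax.vlines(rel, i + 0.5, i + 1.5, color="k", lw=0.5)
    ax.axvline(0.0, color="r", lw=1, label="CS onset")
    ax.set_xlim(aligned.window)
    ax.set_ylim(0.5, aligned.n_trials + 0.5)
    ax.set_xlabel("time from CS onset (s)")
    ax.set_ylabel("trial")
    ax.set_title(f"unit {aligned.unit_id}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_population_profile(profiles: list[PopulationProfile], path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(6, 3))
    for pop in profiles:
        x = pop.window[0] + pop.bin_width * (np.arange(pop.mean_z.size) + 0.5)
        ax.plot(x, pop.mean_z, label=f"Context {pop.context} (n={pop.n_units})")
        if np.all(np.isfinite(pop.se_z)):
            ax.fill_between(x, pop.mean_z - pop.se_z, pop.mean_z + pop.se_z, alpha=0.25)
    ax.axvline(0.0, color="r", lw=1)
    ax.set_xlabel("time from CS onset (s)")
    ax.set_ylabel("Z-score")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
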
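"""Diagnostic plots (all functions take an optional Axes and return it)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .qc import MetageneProfile
from .threshold import ThresholdResult


def plot_metagene(profile: MetageneProfile, ax=None):
    """Footprint 5'-end density versus position relative to the start codon."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(profile.positions, profile.density, width=1.0, color="0.3")
    ax.axvline(0, color="tab:red", lw=0.8, ls="--", label="start codon")
    ax.set_xlabel("position relative to start codon (nt)")
    ax.set_ylabel("normalised 5'-end density")
    ax.legend(frameon=False)
    return ax


def plot_threshold(result: ThresholdResult, ax=None):
    """Observed vs binomially predicted replicate-fraction SD by mean count,
    with the selected threshold dashed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bins = result.bins
    x = np.array([b.mean_total / 2 for b in bins])
    ax.plot(x, [b.observed_sd for b in bins], "o-", label="observed SD")
    ax.plot(x, [b.predicted_sd for b in bins], "s--", label="binomial prediction")
    if result.threshold_count is not None:
        ax.axvline(
            result.threshold_count,
            color="k",
            ls="--",
            lw=0.8,
            label="selected threshold",
        )
    ax.set_xscale("log")
    ax.set_xlabel("mean reads per gene")
    ax.set_ylabel("SD of replicate fraction")
    ax.legend(frameon=False)
    return ax


def plot_te_ecdf(log_ratios_top, log_ratios_nontop, ax=None):
    """Empirical CDFs of log TE ratios for TOP vs non-TOP genes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for vals, label, color in (
        (log_ratios_top, "TOP", "tab:red"),
        (log_ratios_nontop, "non-TOP", "0.3"),
    ):
        x = np.sort(np.asarray(vals, dtype=float))
        ax.step(x, np.arange(1, x.size + 1) / x.size, where="post", label=label, color=color)
    ax.set_xlabel("log TE ratio (exercise / control)")
    ax.set_ylabel("ECDF")
    ax.legend(frameon=False)
    return ax
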
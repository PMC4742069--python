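"""Minimum-expression thresholding by binomial partitioning of replicate reads.

A gene's reads split between two biological replicates like a binomial draw:
with library-size fraction p, the replicate fraction f = A/(A+B) has
counting-noise SD sqrt(p(1-p)/N) for N total reads.  Genes are binned by
mean read count; in each bin the observed SD of f is compared with this
prediction.  At low counts, counting noise dominates and observed tracks
predicted; above some count, biological inter-animal variation makes the
observed SD stably larger.  The lower RPM edge of the first bin where that
excess persists is selected as the minimum expression threshold for
downstream quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinStats:
    """Observed vs binomially predicted replicate-fraction SD in one count bin."""

    bin_index: int
    count_low: float  # bin edges in mean reads per gene (N/2 scale)
    count_high: float
    mean_total: float  # mean N = A + B over genes in the bin
    n_genes: int
    observed_sd: float
    predicted_sd: float


@dataclass(frozen=True)
class ThresholdResult:
    threshold_rpm: float | None
    threshold_count: float | None  # same edge on the mean-count scale
    bins: list[BinStats]
    excess_factor: float
    run_length: int
    p: float

    @property
    def found(self) -> bool:
        return self.threshold_rpm is not None

    def bins_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.bins])


def replicate_fraction(
    counts_a: pd.Series, counts_b: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Per-gene fraction f = A/(A+B) and total N = A+B.

    Genes with N = 0 carry no information about partitioning and are
    excluded (logged).  With equal library sizes and perfect
    reproducibility the fraction is 0.5.
    """
    if not counts_a.index.equals(counts_b.index):
        counts_b = counts_b.reindex(counts_a.index)
        if counts_b.isna().any():
            raise ValueError("replicates do not share a gene set")
    total = counts_a + counts_b
    keep = total > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("replicate_fraction: excluded %d gene(s) with zero total count", n_drop)
    total = total[keep]
    frac = counts_a[keep] / total
    return frac.rename("fraction"), total.rename("total")


def predict_binomial_sd(mean_total: float, p: float = 0.5) -> float:
    """Counting-noise SD of the replicate fraction: sqrt(p(1-p)/N)."""
    if mean_total <= 0:
        raise ValueError("mean total count must be > 0")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return float(np.sqrt(p * (1 - p) / mean_total))


def bin_fraction_sd(
    fractions: pd.Series,
    totals: pd.Series,
    n_bins: int = 20,
    p: float = 0.5,
    min_genes: int = 5,
) -> list[BinStats]:
    """Bin genes by mean count (N/2) on a log10 grid and compute per-bin
    observed and predicted SD of the replicate fraction.

    Bin edges are log-spaced between the 1st and 99th percentile of the
    mean count; bins holding fewer than ``min_genes`` genes are dropped
    with a warning.
    """
    if len(fractions) < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {len(fractions)}")
    mean_count = totals.to_numpy(dtype=float) / 2.0
    lo, hi = np.percentile(mean_count, [1, 99])
    if lo <= 0:
        lo = mean_count[mean_count > 0].min()
    if np.isclose(lo, hi):  # degenerate spread: one bin holds everything
        edges = np.array([lo * 0.999] + [hi * 1.001] * n_bins)
        idx = np.zeros(mean_count.size, dtype=int)
    else:
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
        idx = np.digitize(mean_count, edges) - 1
        idx[mean_count == edges[-1]] = n_bins - 1  # close the top edge

    out: list[BinStats] = []
    f = fractions.to_numpy(dtype=float)
    n = totals.to_numpy(dtype=float)
    for b in range(n_bins):
        mask = idx == b
        n_genes = int(mask.sum())
        if n_genes < min_genes:
            if n_genes:
                log.warning("bin %d dropped: only %d gene(s)", b, n_genes)
            continue
        mean_total = float(n[mask].mean())
        out.append(
            BinStats(
                bin_index=b,
                count_low=float(edges[b]),
                count_high=float(edges[b + 1]),
                mean_total=mean_total,
                n_genes=n_genes,
                observed_sd=float(np.std(f[mask], ddof=1)),
                predicted_sd=predict_binomial_sd(mean_total, p),
            )
        )
    return out


def select_threshold(
    bins: list[BinStats],
    excess_factor: float = 1.2,
    run_length: int = 3,
    mean_library_size: float | None = None,
    p: float = 0.5,
) -> ThresholdResult:
    """Select the minimum-expression threshold from binned fraction SDs.

    "Stably larger than counting statistics" is operationalised as: the
    first bin from which at least ``run_length`` consecutive bins all show
    observed_sd >= excess_factor * predicted_sd.  The threshold is that
    bin's lower edge, converted to RPM via ``mean_library_size``; if no such
    run exists the result carries ``threshold_rpm=None`` ("no threshold").
    """
    if len(bins) < run_length:
        raise ValueError(f"need at least {run_length} bins, got {len(bins)}")
    excess = [b.observed_sd >= excess_factor * b.predicted_sd for b in bins]
    start = None
    for i in range(len(bins) - run_length + 1):
        if all(excess[i : i + run_length]):
            start = i
            break
    if start is None:
        return ThresholdResult(None, None, bins, excess_factor, run_length, p)
    edge_count = bins[start].count_low
    rpm = (
        edge_count / mean_library_size * 1e6
        if mean_library_size
        else None
    )
    return ThresholdResult(rpm, edge_count, bins, excess_factor, run_length, p)


def threshold_analysis(
    counts_a: pd.Series,
    counts_b: pd.Series,
    n_bins: int = 20,
    excess_factor: float = 1.2,
    run_length: int = 3,
    min_genes: int = 5,
) -> ThresholdResult:
    """Full pipeline on a replicate pair: fractions, binning, prediction
    (p from the two library sizes), threshold selection."""
    la, lb = float(counts_a.sum()), float(counts_b.sum())
    p = la / (la + lb)
    frac, total = replicate_fraction(counts_a, counts_b)
    bins = bin_fraction_sd(frac, total, n_bins=n_bins, p=p, min_genes=min_genes)
    return select_threshold(
        bins,
        excess_factor=excess_factor,
        run_length=run_length,
        mean_library_size=(la + lb) / 2.0,
        p=p,
    )


def crossover_mean_count(
    sd_bio: float, excess_factor: float = 1.2, p: float = 0.5
) -> float:
    """Mean total count N* where observed SD first exceeds
    excess_factor x predicted.

    With observed^2 = p(1-p)/N + sd_bio^2, the condition
    observed >= k*predicted crosses at N* = p(1-p)(k^2 - 1)/sd_bio^2.
    """
    if excess_factor <= 1:
        raise ValueError("excess_factor must be > 1")
    return p * (1 - p) * (excess_factor**2 - 1) / sd_bio**2


def apply_threshold(
    rpm: pd.DataFrame, threshold_rpm: float, mode: str = "mean"
) -> pd.Index:
    """Genes passing the expression threshold.

    ``mode='mean'`` keeps genes whose mean RPM across all samples exceeds
    the threshold; ``'all'`` requires every sample; ``'any'`` requires one.
    """
    if mode == "mean":
        keep = rpm.mean(axis=1) > threshold_rpm
    elif mode == "all":
        keep = (rpm > threshold_rpm).all(axis=1)
    elif mode == "any":
        keep = (rpm > threshold_rpm).any(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rpm.index[keep]
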
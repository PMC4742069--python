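"""Translational efficiency, the TOP-gene distribution-shift test, and PCA
of expression profiles.

Translational efficiency (TE) is the ratio of normalised footprint counts
to normalised mRNA-Seq counts — a per-transcript translation-rate proxy.
mRNAs with a 5' terminal oligopyrimidine (TOP) motif, largely ribosomal
proteins and translation factors, are acutely repressed when mTOR
signalling falls (as after endurance exercise); the shift test asks, via a
two-sample Kolmogorov-Smirnov statistic, whether the TE log-ratios
(exercise/control) of TOP genes are distributed lower than those of the
remaining genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Annotation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int


@dataclass(frozen=True)
class TopShiftResult:
    ks: KSResult
    median_top: float
    median_nontop: float

    @property
    def top_shifted_down(self) -> bool:
        return self.median_top < self.median_nontop


@dataclass(frozen=True)
class PcaScores:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    variance_explained: np.ndarray  # fraction per component

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def translational_efficiency(
    rpf_rpm: pd.DataFrame,
    mrna_rpm: pd.DataFrame,
    gene_set: pd.Index | list[str],
) -> pd.Series:
    """TE per gene: mean footprint RPM over replicates divided by mean
    mRNA-Seq RPM.  Genes with zero mRNA RPM are excluded (logged)."""
    genes = pd.Index(gene_set)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    rpf = rpf_rpm.loc[genes].mean(axis=1)
    mrna = mrna_rpm.loc[genes].mean(axis=1)
    ok = mrna > 0
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("TE: excluded %d gene(s) with zero mRNA RPM", n_drop)
    return (rpf[ok] / mrna[ok]).rename("te")


def te_shift(
    rpf_rpm_control: pd.DataFrame,
    rpf_rpm_exercise: pd.DataFrame,
    mrna_rpm_control: pd.DataFrame,
    mrna_rpm_exercise: pd.DataFrame,
    gene_set: pd.Index | list[str],
    per_replicate: bool = False,
) -> pd.DataFrame:
    """TE per condition and the log TE ratio (exercise/control) per gene.

    By default replicate columns are averaged per condition before the
    ratio; with ``per_replicate`` TE is computed per replicate and then
    averaged.  Returns columns te_control, te_exercise, log_ratio (natural
    log); genes with a zero denominator in either condition are dropped.
    """
    if per_replicate:
        def _te(rpf: pd.DataFrame, mrna: pd.DataFrame) -> pd.Series:
            parts = [
                translational_efficiency(rpf[[c1]], mrna[[c2]], gene_set)
                for c1, c2 in zip(rpf.columns, mrna.columns)
            ]
            return pd.concat(parts, axis=1).mean(axis=1)

        te_c = _te(rpf_rpm_control, mrna_rpm_control)
        te_e = _te(rpf_rpm_exercise, mrna_rpm_exercise)
    else:
        te_c = translational_efficiency(rpf_rpm_control, mrna_rpm_control, gene_set)
        te_e = translational_efficiency(rpf_rpm_exercise, mrna_rpm_exercise, gene_set)
    df = pd.DataFrame({"te_control": te_c, "te_exercise": te_e}).dropna()
    df = df[(df["te_control"] > 0) & (df["te_exercise"] > 0)]
    df["log_ratio"] = np.log(df["te_exercise"] / df["te_control"])
    return df


def ks_two_sample(values1, values2) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over observed points of the ECDF difference; the
    p-value uses the asymptotic Kolmogorov distribution with effective size
    n1*n2/(n1+n2).  Two identical degenerate samples give D=0, p=1.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(x, y, method="asymp")
    return KSResult(
        D=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
    )


def top_shift_test(te_table: pd.DataFrame, annotation: Annotation) -> TopShiftResult:
    """KS comparison of log TE ratios between TOP and non-TOP genes, with
    group medians (a TOP median below the non-TOP median is the
    mTOR-suppression direction)."""
    is_top = np.array([annotation[g].is_top for g in te_table.index])
    top = te_table.loc[is_top, "log_ratio"].to_numpy()
    non = te_table.loc[~is_top, "log_ratio"].to_numpy()
    if top.size < 2 or non.size < 2:
        raise ValueError(
            f"both groups need >= 2 genes (TOP: {top.size}, non-TOP: {non.size})"
        )
    return TopShiftResult(
        ks=ks_two_sample(top, non),
        median_top=float(np.median(top)),
        median_nontop=float(np.median(non)),
    )


def pca_profiles(
    rpm: pd.DataFrame,
    gene_set: pd.Index | list[str] | None = None,
    n_components: int | None = None,
    pseudocount: float = 0.5,
) -> PcaScores:
    """PCA of samples over log2(RPM + pseudocount) expression profiles.

    Genes are mean-centred; scores come from the SVD of the samples x genes
    matrix.  Each component's sign is fixed so the loading of the
    alphabetically first gene is non-negative, making scores reproducible
    and invariant to gene ordering.
    """
    if gene_set is not None:
        rpm = rpm.loc[pd.Index(gene_set)]
    n_samples = rpm.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    max_comp = min(n_samples, rpm.shape[0])
    if n_components is None:
        n_components = min(n_samples - 1, max_comp)
    if n_components > max_comp:
        raise ValueError(f"cannot extract {n_components} components from {max_comp}")

    rpm = rpm.sort_index()
    X = np.log2(rpm.to_numpy(dtype=float).T + pseudocount)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((S**2).sum())
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    flip = np.where(loadings[:, 0] < 0, -1.0, 1.0)
    scores = scores * flip
    var_frac = S[:n_components] ** 2 / total_var if total_var > 0 else np.zeros(n_components)
    return PcaScores(
        sample_ids=list(rpm.columns),
        scores=scores,
        variance_explained=var_frac,
    )
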
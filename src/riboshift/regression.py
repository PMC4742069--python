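"""Per-group correlations and backward-elimination regression for the
expression panel.

The panel records, per mouse, Slc25a25 protein abundance (densitometry)
and eight candidate regulator transcripts (qPCR relative expression).
Association is assessed two ways: simple Pearson correlations within each
time-point group, and one pooled multiple linear regression across the
selected groups in which the least significant predictor is repeatedly
removed and the model refit, leaving the predictors that jointly explain
protein abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import PANEL_PREDICTORS, PANEL_RESPONSE


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient (collinear predictors)."""


@dataclass(frozen=True)
class RegressionModel:
    predictors: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    intercept: float | None
    r_squared: float
    n: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "t": self.t_values,
                "p_value": self.p_values,
            }
        )


@dataclass(frozen=True)
class EliminationTrace:
    models: list[RegressionModel]
    removed: list[str]

    @property
    def final(self) -> RegressionModel:
        return self.models[-1]


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, R = np.linalg.qr(X.to_numpy(dtype=float))
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    return [c for c, d in zip(X.columns, diag) if d <= tol]


def ols_fit(
    X: pd.DataFrame, y: pd.Series, add_intercept: bool = True
) -> RegressionModel:
    """Ordinary least squares of y on the predictor columns of X.

    Standard errors use the residual variance with n - p - 1 df (n - p
    without intercept); p-values are two-sided from the t distribution.
    Rank deficiency raises :class:`RankDeficiencyError` naming the
    collinear column(s).
    """
    n, p = X.shape
    n_params = p + (1 if add_intercept else 0)
    if n <= n_params:
        raise ValueError(f"need n > {n_params} observations for {p} predictors, got {n}")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(design.to_numpy(dtype=float)) < design.shape[1]:
        bad = _collinear_columns(design)
        raise RankDeficiencyError(f"collinear design column(s): {bad}")
    res = sm.OLS(np.asarray(y, dtype=float), design).fit()
    params = pd.Series(res.params, index=design.columns)
    se = pd.Series(res.bse, index=design.columns)
    t = pd.Series(res.tvalues, index=design.columns)
    pv = pd.Series(res.pvalues, index=design.columns)
    keep = list(X.columns)
    return RegressionModel(
        predictors=keep,
        coefficients=params[keep],
        std_errors=se[keep],
        t_values=t[keep],
        p_values=pv[keep],
        intercept=float(params["const"]) if add_intercept else None,
        r_squared=float(res.rsquared),
        n=int(n),
    )


def backward_eliminate(
    X: pd.DataFrame,
    y: pd.Series,
    alpha_stay: float = 0.3,
    min_predictors: int = 1,
    add_intercept: bool = True,
) -> EliminationTrace:
    """Backward elimination: repeatedly refit OLS and drop the predictor
    with the largest p-value while that p-value exceeds ``alpha_stay`` and
    more than ``min_predictors`` remain.  The full removal trace is
    returned so any stopping rule can be audited.
    """
    X = X.copy()
    models = [ols_fit(X, y, add_intercept=add_intercept)]
    removed: list[str] = []
    while X.shape[1] > min_predictors:
        current = models[-1]
        worst = current.p_values.idxmax()
        if current.p_values[worst] <= alpha_stay:
            break
        X = X.drop(columns=[worst])
        removed.append(str(worst))
        models.append(ols_fit(X, y, add_intercept=add_intercept))
    return EliminationTrace(models=models, removed=removed)


def group_correlations(
    panel: pd.DataFrame,
    groups: tuple[str, ...] = ("NoEx", "0h", "1h"),
    response: str = PANEL_RESPONSE,
    predictors: tuple[str, ...] = PANEL_PREDICTORS,
) -> pd.DataFrame:
    """Pearson r between the response and each predictor within each group.

    Returns an edge list (group, predictor, r, n) suitable for network
    export; r is NaN where a column is constant within the group (the
    correlation is then undefined).
    """
    rows = []
    for group in groups:
        sub = panel[panel["group"] == group]
        if len(sub) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 mice")
        yv = sub[response].to_numpy(dtype=float)
        for pred in predictors:
            xv = sub[pred].to_numpy(dtype=float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(xv, yv)[0, 1])
            rows.append({"group": group, "predictor": pred, "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def panel_regression(
    panel: pd.DataFrame,
    groups: tuple[str, ...] = ("NoEx", "0h", "1h"),
    alpha_stay: float = 0.3,
    min_predictors: int = 1,
    add_intercept: bool = True,
    predictors: tuple[str, ...] = PANEL_PREDICTORS,
    response: str = PANEL_RESPONSE,
) -> EliminationTrace:
    """Pooled backward-elimination regression of protein abundance on the
    predictor transcripts over the selected groups (no group dummies)."""
    sub = panel[panel["group"].isin(groups)]
    X = sub.loc[:, list(predictors)].astype(float)
    y = sub[response].astype(float)
    return backward_eliminate(
        X,
        y,
        alpha_stay=alpha_stay,
        min_predictors=min_predictors,
        add_intercept=add_intercept,
    )
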
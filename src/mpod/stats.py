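"""Cohort-level variable reduction and regression.

The workflow mirrors the standard psychometric-style reduction used on
per-eye MPOD/morphometry tables: principal-components factor analysis of the
correlation matrix flags redundant variables (|loading| > 0.7 taken as a
significant loading; Kaiser eigenvalue > 1 retention by default, optional
varimax rotation), after which the surviving variables enter ordinary and
forward-stepwise multiple regression on standardised scales.  A coefficient
of determination below 0.5 is flagged as unlikely to be useful for
prediction.

Eyes missing a derived feature (e.g. profiles without a dd4) are dropped
listwise per analysis, so each analysis uses its own complete-case n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, DegenerateVariableError

__all__ = [
    "FactorResult",
    "RegressionResult",
    "factor_analysis",
    "multiple_regression",
    "stepwise_forward",
]


@dataclass(frozen=True)
class FactorResult:
    """Principal-components factor analysis output.

    loadings : variables x retained factors (correlation-scale)
    loadings_full : variables x all components, reproduces the correlation
        matrix as L @ L.T
    variance_explained : per-retained-factor fraction of total variance
    significant : boolean mask, |loading| > threshold
    eigenvalues : all eigenvalues, descending
    n_used : complete-case rows used
    """

    loadings: pd.DataFrame
    loadings_full: pd.DataFrame
    variance_explained: np.ndarray
    significant: pd.DataFrame
    eigenvalues: np.ndarray
    n_used: int


@dataclass(frozen=True)
class RegressionResult:
    """Standardised-scale regression output.

    betas : standardised slopes per predictor
    r2 : coefficient of determination
    useful : r2 >= 0.5, the conventional usefulness bar
    selected_order : predictor entry ranking (stepwise only)
    stepwise_r2_increments : per-step R2 increase (stepwise only); the
        increments sum to the final stepwise r2 exactly
    n_used : complete-case rows used
    """

    betas: pd.Series
    r2: float
    useful: bool
    n_used: int
    selected_order: list[str] | None = None
    stepwise_r2_increments: list[float] | None = None


def _complete_cases(table: pd.DataFrame, columns) -> pd.DataFrame:
    sub = table.loc[:, list(columns)].apply(pd.to_numeric)
    return sub.dropna()


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise DegenerateVariableError(
            f"constant column(s): {', '.join(constant.index)}")
    return (df - df.mean()) / sd


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 200):
    """Varimax rotation of a loading matrix (Kaiser-normalised omitted)."""
    p, k = loadings.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L * (L**2).sum(axis=0)) / p))
        R = u @ vt
        new = s.sum()
        if new <= var * (1 + tol):
            break
        var = new
    return loadings @ R


def factor_analysis(table: pd.DataFrame, variables, n_factors: int | None = None,
                    threshold: float = 0.7, rotate: str | None = None
                    ) -> FactorResult:
    """Principal-components extraction on the correlation matrix.

    Loadings are eigenvector * sqrt(eigenvalue); factors are retained by the
    Kaiser rule (eigenvalue > 1) unless ``n_factors`` is given.  Loadings are
    sign-fixed so each factor's largest-magnitude loading is positive (the
    sign of a factor is arbitrary).  ``rotate="varimax"`` rotates the
    retained loadings.
    """
    variables = list(variables)
    sub = _complete_cases(table, variables)
    if len(sub) < 3:
        raise ValueError("factor analysis needs at least 3 complete rows")
    z = _standardize(sub)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    w, v = np.linalg.eigh(corr)
    if w[0] < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    loadings_full = v * np.sqrt(w)[None, :]

    k = int(n_factors) if n_factors is not None else max(int(np.sum(w > 1.0)), 1)
    retained = loadings_full[:, :k].copy()
    if rotate == "varimax" and k > 1:
        retained = _varimax(retained)
    elif rotate not in (None, "varimax"):
        raise ValueError(f"unknown rotation {rotate!r}")

    flip = np.sign(retained[np.argmax(np.abs(retained), axis=0),
                            np.arange(retained.shape[1])])
    retained = retained * np.where(flip == 0, 1.0, flip)[None, :]

    var_exp = (retained**2).sum(axis=0) / len(variables)
    if rotate == "varimax":
        idx = np.argsort(var_exp)[::-1]
        retained, var_exp = retained[:, idx], var_exp[idx]

    fac_cols = [f"F{i+1}" for i in range(k)]
    all_cols = [f"F{i+1}" for i in range(loadings_full.shape[1])]
    loadings = pd.DataFrame(retained, index=variables, columns=fac_cols)
    return FactorResult(
        loadings=loadings,
        loadings_full=pd.DataFrame(loadings_full, index=variables, columns=all_cols),
        variance_explained=var_exp,
        significant=loadings.abs() > threshold,
        eigenvalues=w,
        n_used=len(sub),
    )


def _design(table: pd.DataFrame, y: str, predictors: list[str]):
    sub = _complete_cases(table, [y] + predictors)
    n = len(sub)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need more than {len(predictors) + 1} complete rows, got {n}")
    z = _standardize(sub)
    X = z[predictors].to_numpy()
    if predictors and np.linalg.matrix_rank(X) < len(predictors):
        raise CollinearityError("rank-deficient design matrix "
                                f"(predictors: {', '.join(predictors)})")
    return z[y].to_numpy(), X, n


def multiple_regression(table: pd.DataFrame, y: str, predictors
                        ) -> RegressionResult:
    """OLS of standardised ``y`` on standardised predictors.

    Reports standardised betas and R-squared; ``useful`` is False when the
    model explains less than half the variance in ``y``.
    """
    predictors = list(predictors)
    yv, X, n = _design(table, y, predictors)
    res = sm.OLS(yv, X).fit()
    betas = pd.Series(res.params, index=predictors)
    ssr = float(np.sum(res.resid**2))
    r2 = 1.0 - ssr / float(np.sum(yv**2))
    return RegressionResult(betas=betas, r2=r2, useful=r2 >= 0.5, n_used=n)


def stepwise_forward(table: pd.DataFrame, y: str, candidates,
                     alpha_enter: float = 0.05) -> RegressionResult:
    """Forward stepwise regression on standardised variables.

    At each step the candidate with the largest F-to-enter joins the model,
    provided its entry p-value is below ``alpha_enter``; entry order and
    per-step R-squared increments are recorded.
    """
    candidates = list(candidates)
    yv, X, n = _design(table, y, candidates)
    tss = float(np.sum(yv**2))

    selected: list[int] = []
    increments: list[float] = []
    rss = tss
    remaining = list(range(len(candidates)))
    while remaining:
        best = None
        for j in remaining:
            cols = selected + [j]
            beta, res_ss = _ols_rss(X[:, cols], yv)
            df_resid = n - len(cols) - 1      # mean absorbed by standardisation
            if df_resid <= 0:
                continue
            if res_ss <= 0:
                fval, pval = np.inf, 0.0
            else:
                fval = (rss - res_ss) / (res_ss / df_resid)
                pval = float(sps.f.sf(fval, 1, df_resid))
            if best is None or fval > best[0]:
                best = (fval, pval, j, res_ss)
        if best is None or not best[1] < alpha_enter:
            break
        _, _, j, res_ss = best
        selected.append(j)
        remaining.remove(j)
        increments.append((rss - res_ss) / tss)
        rss = res_ss

    names = [candidates[j] for j in selected]
    if selected:
        beta, _ = _ols_rss(X[:, selected], yv)
        betas = pd.Series(beta, index=names)
    else:
        betas = pd.Series(dtype=float)
    r2 = 1.0 - rss / tss
    return RegressionResult(betas=betas, r2=r2, useful=r2 >= 0.5, n_used=n,
                            selected_order=names,
                            stepwise_r2_increments=increments)


def _ols_rss(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)
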
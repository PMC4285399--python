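"""Two-stage multilevel GLMs for trial-level behavior and voxel maps.

Stage one fits an ordinary (or logistic) regression within each subject;
stage two regresses the subject-level coefficients on an intercept plus
between-subject covariates and tests the intercept with a two-tailed t test
(df = subjects - covariates - 1).  This summary-statistics approach matches
inference that reports t statistics with n_subjects - 1 degrees of freedom.

Voxel-wise second-level analysis uses iteratively reweighted least squares
with Tukey's bisquare weights (tuning constant 4.685, MAD scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .params import TEMP_CENTER_C

__all__ = [
    "SubjectCoefficients",
    "fit_subject_linear",
    "fit_subject_logistic",
    "group_level_test",
    "robust_group_regression",
]

#: logistic coefficients beyond this bound are treated as diverging (separation)
_SEPARATION_BOUND = 15.0


@dataclass
class SubjectCoefficients:
    subject: object
    beta: pd.Series              # coefficient per predictor
    cov: pd.DataFrame            # coefficient covariance
    n_trials: int
    converged: bool = True
    model: str = "linear"


def _behavior_design(trials: pd.DataFrame, interaction: bool = True) -> pd.DataFrame:
    """Within-subject predictors: regulation code, centered temperature, interaction."""
    d = trials.loc[~trials["excluded"].astype(bool)]
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "reg_code": d["reg_code"].astype(float),
            "temp_centered": d["temp_c"].astype(float) - TEMP_CENTER_C,
        },
        index=d.index,
    )
    if interaction:
        X["reg_x_temp"] = X["reg_code"] * X["temp_centered"]
    return X


def _check_degenerate(X: pd.DataFrame) -> None:
    for name in X.columns:
        if name != "intercept" and X[name].nunique() < 2:
            raise ValueError(f"predictor {name!r} is constant within subject")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.drop(columns="intercept").to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        names = X.drop(columns="intercept").columns
        raise ValueError(f"collinear predictors: {names[i]!r} and {names[j]!r}")


def fit_subject_linear(
    trials: pd.DataFrame, outcome: str = "rating", interaction: bool = True
) -> SubjectCoefficients:
    """Within-subject OLS of ratings on regulation, temperature, interaction."""
    X = _behavior_design(trials, interaction)
    _check_degenerate(X)
    y = trials.loc[X.index, outcome].astype(float)
    res = sm.OLS(y, X).fit()
    return SubjectCoefficients(
        subject=trials["subject"].iloc[0],
        beta=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        n_trials=len(X),
        model="linear",
    )


def fit_subject_logistic(
    trials: pd.DataFrame, outcome: str = "decision", interaction: bool = True
) -> SubjectCoefficients:
    """Within-subject ML logistic regression of the pain/no-pain decision.

    A subject with only one outcome class, or with separation (diverging
    coefficients / non-convergence), gets ``converged=False`` and should be
    excluded from the group stage.
    """
    X = _behavior_design(trials, interaction)
    y = trials.loc[X.index, outcome].astype(float)
    subject = trials["subject"].iloc[0]
    if y.nunique() < 2:
        nan = pd.Series(np.nan, index=X.columns)
        return SubjectCoefficients(
            subject=subject, beta=nan,
            cov=pd.DataFrame(np.nan, index=X.columns, columns=X.columns),
            n_trials=len(X), converged=False, model="logistic",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res, converged = None, False
    if res is not None and np.any(np.abs(res.params.to_numpy()) > _SEPARATION_BOUND):
        converged = False  # monotone likelihood: coefficients diverging
    if res is None:
        beta = pd.Series(np.nan, index=X.columns)
        cov = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
    else:
        beta = res.params
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return SubjectCoefficients(
        subject=subject, beta=beta, cov=cov, n_trials=len(X),
        converged=converged, model="logistic",
    )


def group_level_test(
    subject_coeffs: list, between_covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Population test of each within-subject coefficient.

    Non-converged subjects are dropped.  ``between_covariates`` is indexed by
    subject (e.g. regulation-run order coded +1/-1); constant covariates are
    dropped with a warning.  Returns one row per predictor with the
    population estimate (the intercept of the second-level regression), its
    SE, t, df, and a two-tailed p; a zero-residual second level is reported
    with ``degenerate=True``.
    """
    usable = [c for c in subject_coeffs if c.converged]
    if len(usable) < 3:
        raise ValueError("need at least 3 converged subjects")
    n = len(usable)
    betas = pd.DataFrame(
        {c.subject: c.beta for c in usable}
    ).T.rename_axis("subject")

    Z = pd.DataFrame({"intercept": np.ones(n)}, index=betas.index)
    if between_covariates is not None:
        cov = between_covariates.loc[betas.index]
        for name in cov.columns:
            if cov[name].nunique() < 2:
                warnings.warn(f"between-subject covariate {name!r} is constant; dropped")
            else:
                Z[name] = cov[name].astype(float)
    q = Z.shape[1]
    df = n - q
    rows = []
    Zm = Z.to_numpy()
    pinv = np.linalg.pinv(Zm)
    h = np.linalg.inv(Zm.T @ Zm)[0, 0]  # variance factor of the intercept
    for name in betas.columns:
        y = betas[name].to_numpy()
        gamma = pinv @ y
        resid = y - Zm @ gamma
        sigma2 = float(resid @ resid) / df if df > 0 else np.nan
        se = np.sqrt(sigma2 * h)
        scale = max(1.0, abs(gamma[0]))
        degenerate = not np.isfinite(se) or se <= 1e-12 * scale
        if degenerate:
            t = np.inf if gamma[0] > 0 else (-np.inf if gamma[0] < 0 else 0.0)
            p = 0.0 if gamma[0] != 0 else 1.0
        else:
            t = gamma[0] / se
            p = 2 * stats.t.sf(abs(t), df)
        rows.append(
            {"predictor": name, "beta_hat": gamma[0], "se": se, "t": t,
             "df": df, "p": p, "n_subjects": n, "degenerate": degenerate}
        )
    return pd.DataFrame(rows).set_index("predictor")


def robust_group_regression(
    maps: np.ndarray, covariate: np.ndarray | None = None, max_iter: int = 50
):
    """Voxel-wise robust second-level regression across subjects.

    ``maps`` is (n_subjects, n_voxels); ``covariate`` an optional
    (n_subjects,) or (n_subjects, q) matrix.  Returns a dict of arrays
    ``beta``/``t``/``p`` of shape (1+q, n_voxels) (row 0 = group intercept)
    plus an ``ols_fallback`` boolean per voxel for non-converged IRLS fits.
    """
    maps = np.asarray(maps, dtype=float)
    n_subj, n_vox = maps.shape
    if n_subj < 5:
        raise ValueError("need at least 5 subjects")
    Z = np.ones((n_subj, 1))
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        Z = np.hstack([Z, cov - cov.mean(axis=0)])
    q = Z.shape[1]
    beta = np.empty((q, n_vox))
    tval = np.empty((q, n_vox))
    pval = np.empty((q, n_vox))
    fallback = np.zeros(n_vox, dtype=bool)
    norm = sm.robust.norms.TukeyBiweight(c=4.685)
    for v in range(n_vox):
        y = maps[:, v]
        try:
            res = sm.RLM(y, Z, M=norm).fit(maxiter=max_iter, scale_est="mad")
            ok = np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
        except Exception:
            res, ok = None, False
        if not ok:
            fallback[v] = True
            res = sm.OLS(y, Z).fit()
        beta[:, v] = res.params
        se = res.bse
        with np.errstate(divide="ignore", invalid="ignore"):
            tval[:, v] = res.params / se
        pval[:, v] = 2 * stats.t.sf(np.abs(tval[:, v]), n_subj - q)
    return {"beta": beta, "t": tval, "p": pval, "ols_fallback": fallback, "df": n_subj - q}
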
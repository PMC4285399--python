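"""Multilevel two-path and three-path mediation with bootstrap inference.

First level: per-subject OLS path models over trials.  For the two-path
(three-variable) model the system is

    y = c x + e_y           (total effect)
    m = a x + e_m           (predictor -> mediator)
    y = c' x + b m + e'_y   (direct + mediator -> outcome)

so the indirect effect is a*b = c - c' (exactly, in single-level OLS without
covariates).  The three-path chain x -> m1 -> m2 -> y adds one equation and
the indirect effect is the product b1*b2*b3.

Second level: subject rows of path coefficients are combined by
inverse-variance weights (within-subject OLS variance plus a
method-of-moments between-subject component) and tested by bootstrap:
subject rows are resampled jointly with replacement, the weighted column
mean is recomputed per draw, and two-tailed p-values come from the tail
shares of the bootstrap distribution (floored at 2/n_boot).  Three-path
mediation is declared only when the joint-significance criterion (all three
paths individually significant) and the bootstrap product-of-coefficients
test both pass.

Product variances for the weighting use the second-order two-path formula
Var(ab) = a^2 var_b + b^2 var_a + var_a var_b and the first-order
multivariate delta form for three paths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectPathEstimates",
    "ThreePathEstimates",
    "PathSummary",
    "MediationResult",
    "fit_two_path_subject",
    "fit_three_path_subject",
    "sobel_variance",
    "delta_variance_product3",
    "inverse_variance_weights",
    "bootstrap_paths",
    "multilevel_mediation",
    "multilevel_three_path",
    "mediation_brain_search",
]

logger = logging.getLogger(__name__)

TWO_PATH_NAMES = ["a", "b", "c_prime", "c", "ab"]
THREE_PATH_NAMES = ["b1", "b2", "b3", "product"]


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS coefficients and their sampling variances (homoscedastic)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("collinear predictors in path regression")
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    var = sigma2 * np.diag(np.linalg.inv(X.T @ X))
    return coef, var


def _with_intercept(x, covariates=None, *extra):
    cols = [np.ones(len(x)), np.asarray(x, dtype=float)]
    cols.extend(np.asarray(e, dtype=float) for e in extra)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


@dataclass
class SubjectPathEstimates:
    subject: object
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    var_a: float
    var_b: float
    var_c: float
    var_c_prime: float
    var_ab: float
    covariates: tuple = ()

    def row(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c_prime, self.c, self.ab])

    def var_row(self) -> np.ndarray:
        return np.array(
            [self.var_a, self.var_b, self.var_c_prime, self.var_c, self.var_ab]
        )


@dataclass
class ThreePathEstimates:
    subject: object
    b1: float
    b2: float
    b3: float
    product: float
    var_b1: float
    var_b2: float
    var_b3: float
    delta_var_product: float
    covariates: tuple = ()

    def row(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.product])

    def var_row(self) -> np.ndarray:
        return np.array(
            [self.var_b1, self.var_b2, self.var_b3, self.delta_var_product]
        )


@dataclass
class PathSummary:
    estimate: float
    se: float
    p: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class MediationResult:
    paths: dict                  # name -> PathSummary
    n_boot: int
    seed: int
    alpha: float
    n_subjects: int
    significant: bool
    joint_significant: bool | None = None
    subject_estimates: list = field(default_factory=list, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {
                    "estimate": s.estimate, "se": s.se, "p": s.p,
                    "ci_low": s.ci_low, "ci_high": s.ci_high,
                }
                for name, s in self.paths.items()
            }
        ).T


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------

def fit_two_path_subject(
    x, m, y, covariates=None, subject=None
) -> SubjectPathEstimates:
    """Per-subject two-path model: three OLS fits sharing the covariate block."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    q = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    if len(x) <= q + 3:
        raise ValueError("too few trials for the two-path model")
    Xc = _with_intercept(x, covariates)
    coef_c, var_c = _ols(y, Xc)
    coef_a, var_a = _ols(m, Xc)
    Xb = _with_intercept(x, covariates, m)  # columns: 1, x, m, cov...
    coef_b, var_b = _ols(y, Xb)
    a, b = coef_a[1], coef_b[2]
    return SubjectPathEstimates(
        subject=subject,
        a=a, b=b, c=coef_c[1], c_prime=coef_b[1], ab=a * b,
        var_a=var_a[1], var_b=var_b[2], var_c=var_c[1], var_c_prime=var_b[1],
        var_ab=sobel_variance(a, b, var_a[1], var_b[2]),
        covariates=() if covariates is None else ("cov",) * q,
    )


def fit_three_path_subject(
    x, m1, m2, y, covariates=None, subject=None
) -> ThreePathEstimates:
    """Per-subject three-path chain: four OLS fits (x -> m1 -> m2 -> y)."""
    x = np.asarray(x, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    y = np.asarray(y, dtype=float)
    coef1, var1 = _ols(m1, _with_intercept(x, covariates))
    X2 = _with_intercept(x, covariates, m1)
    coef2, var2 = _ols(m2, X2)
    X3 = _with_intercept(x, covariates, m1, m2)
    coef3, var3 = _ols(y, X3)
    b1, b2, b3 = coef1[1], coef2[2], coef3[3]
    return ThreePathEstimates(
        subject=subject,
        b1=b1, b2=b2, b3=b3, product=b1 * b2 * b3,
        var_b1=var1[1], var_b2=var2[2], var_b3=var3[3],
        delta_var_product=delta_variance_product3(
            b1, b2, b3, var1[1], var2[2], var3[3]
        ),
    )


# ---------------------------------------------------------------------------
# variance estimators for products
# ---------------------------------------------------------------------------

def sobel_variance(a, b, var_a, var_b, second_order: bool = True):
    """Variance of the product of two independent path estimates.

    Second order (exact for independent normals):
    a^2 var_b + b^2 var_a + var_a var_b; the first-order form drops the
    var_a var_b term.
    """
    if np.any(np.asarray(var_a) < 0) or np.any(np.asarray(var_b) < 0):
        raise ValueError("variances must be non-negative")
    out = a**2 * var_b + b**2 * var_a
    if second_order:
        out = out + var_a * var_b
    return out


def delta_variance_product3(b1, b2, b3, var_b1, var_b2, var_b3):
    """First-order multivariate-delta variance of b1*b2*b3 (independent paths)."""
    for v in (var_b1, var_b2, var_b3):
        if np.any(np.asarray(v) < 0):
            raise ValueError("variances must be non-negative")
    return (b2 * b3) ** 2 * var_b1 + (b1 * b3) ** 2 * var_b2 + (b1 * b2) ** 2 * var_b3


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------

def inverse_variance_weights(estimates: np.ndarray, within_var: np.ndarray) -> np.ndarray:
    """Per-subject, per-path weights 1/(within + between) normalized to sum 1.

    The between-subject component is method-of-moments:
    tau^2 = max(0, var(estimates) - mean(within_var)).
    """
    est = np.asarray(estimates, dtype=float)
    wv = np.asarray(within_var, dtype=float)
    tau2 = np.maximum(0.0, est.var(axis=0, ddof=1) - wv.mean(axis=0))
    w = 1.0 / (wv + tau2)
    return w / w.sum(axis=0, keepdims=True)


def _expanded_tail_p(share: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p from the smaller bootstrap tail share, small-sample expanded.

    The raw percentile rule p = 2*share is anticonservative for small n
    because bootstrap dispersion understates sampling uncertainty; the
    expanded-percentile correction maps the tail share through a normal
    quantile and refers it to a Student t with n-1 df, scaled by
    sqrt(n/(n-1)) (Efron's interval expansion, applied to p-values).
    """
    from scipy import stats as _st

    c = np.sqrt(n / (n - 1.0))
    z = _st.norm.isf(np.clip(share, 1e-12, 0.5))
    return 2.0 * _st.t.sf(z / c, n - 1)


def _expanded_ci_level(alpha: float, n: int) -> float:
    """Percentile level for the expanded (1 - alpha) CI, consistent with the p rule."""
    from scipy import stats as _st

    c = np.sqrt(n / (n - 1.0))
    return float(_st.norm.cdf(-c * _st.t.isf(alpha / 2.0, n - 1)))


def _se_expansion_factor(n: int, alpha: float = 0.05) -> float:
    from scipy import stats as _st

    c = np.sqrt(n / (n - 1.0))
    return float(c * _st.t.isf(alpha / 2.0, n - 1) / _st.norm.isf(alpha / 2.0))


def bootstrap_paths(
    path_matrix: np.ndarray,
    weights: np.ndarray | None = None,
    n_boot: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    names: list | None = None,
    small_sample: bool = True,
) -> dict:
    """Bootstrap the (weighted) mean of each path column over subject rows.

    Rows are resampled jointly so cross-path dependence is preserved.
    Two-tailed p comes from the smaller tail share of the bootstrap
    distribution (floored at 2/n_boot) and, by default, is passed through
    the small-sample expansion of :func:`_expanded_tail_p`; CI quantile
    levels and the reported SE receive the matching expansion so the
    significance flag, the CI excluding zero, and p < alpha always agree.
    """
    P = np.asarray(path_matrix, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n, k = P.shape
    if n < 5:
        raise ValueError("need at least 5 subjects for the bootstrap")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    if weights is None:
        W = np.ones((n, k))
    else:
        W = np.asarray(weights, dtype=float)
        if W.ndim == 1:
            W = np.repeat(W[:, None], k, axis=1)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)  # (n_boot, n)
    num = counts @ (W * P)      # (n_boot, k)
    den = counts @ W
    stats_ = num / den

    point = (W * P).sum(axis=0) / W.sum(axis=0)
    se = stats_.std(axis=0, ddof=1)
    level = _expanded_ci_level(alpha, n) if small_sample else alpha / 2.0
    lo = np.quantile(stats_, level, axis=0)
    hi = np.quantile(stats_, 1 - level, axis=0)
    share = np.minimum((stats_ <= 0).mean(axis=0), (stats_ >= 0).mean(axis=0))
    if small_sample:
        p = _expanded_tail_p(share, n)
        se = se * _se_expansion_factor(n, alpha)
    else:
        p = 2.0 * share
    floor = 2.0 / n_boot
    degenerate = se == 0
    if degenerate.any():
        warnings.warn("degenerate bootstrap distribution for some paths")
    p = np.clip(p, floor, 1.0)

    names = names or [f"path_{j}" for j in range(k)]
    return {
        "names": names,
        "estimate": point,
        "se": se,
        "p": p,
        "ci_low": lo,
        "ci_high": hi,
        "n_boot": n_boot,
        "seed": seed,
    }


def _result_from_bootstrap(boot, alpha, n_subjects, seed, product_name,
                           joint_names=None, subject_estimates=()):
    paths = {
        name: PathSummary(
            estimate=float(boot["estimate"][j]), se=float(boot["se"][j]),
            p=float(boot["p"][j]), ci_low=float(boot["ci_low"][j]),
            ci_high=float(boot["ci_high"][j]),
        )
        for j, name in enumerate(boot["names"])
    }
    joint = None
    if joint_names is not None:
        joint = all(paths[nm].p < alpha for nm in joint_names)
    product_sig = paths[product_name].p < alpha
    significant = product_sig if joint is None else (product_sig and joint)
    return MediationResult(
        paths=paths, n_boot=boot["n_boot"], seed=seed, alpha=alpha,
        n_subjects=n_subjects, significant=significant, joint_significant=joint,
        subject_estimates=list(subject_estimates),
    )


def _per_subject_arrays(data: pd.DataFrame, names: list):
    for subject, d in data.groupby("subject"):
        d = d.loc[~d.get("excluded", pd.Series(False, index=d.index)).astype(bool)]
        yield subject, [d[nm].to_numpy(dtype=float) for nm in names]


def multilevel_mediation(
    data: pd.DataFrame,
    x: str, m: str, y: str,
    covariates: list | None = None,
    n_boot: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    weighted: bool = True,
) -> MediationResult:
    """Two-path multilevel mediation over a tidy trial table.

    ``data`` needs a ``subject`` column plus the named variable columns;
    rows flagged ``excluded`` are dropped.  Subjects whose first-level fit
    fails are dropped with a log message; fewer than 5 usable subjects is an
    error.
    """
    cov_names = list(covariates or [])
    estimates = []
    for subject, arrs in _per_subject_arrays(data, [x, m, y] + cov_names):
        xv, mv, yv = arrs[:3]
        cov = np.column_stack(arrs[3:]) if cov_names else None
        try:
            estimates.append(
                fit_two_path_subject(xv, mv, yv, covariates=cov, subject=subject)
            )
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("subject %s dropped from mediation: %s", subject, err)
    if len(estimates) < 5:
        raise ValueError("fewer than 5 usable subjects")
    P = np.array([e.row() for e in estimates])
    V = np.array([e.var_row() for e in estimates])
    W = inverse_variance_weights(P, V) if weighted else None
    boot = bootstrap_paths(P, W, n_boot=n_boot, seed=seed, alpha=alpha,
                           names=TWO_PATH_NAMES)
    return _result_from_bootstrap(
        boot, alpha, len(estimates), seed, product_name="ab",
        subject_estimates=estimates,
    )


def multilevel_three_path(
    data: pd.DataFrame,
    x: str, m1: str, m2: str, y: str,
    covariates: list | None = None,
    n_boot: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    weighted: bool = True,
) -> MediationResult:
    """Three-path multilevel mediation (x -> m1 -> m2 -> y) over a trial table.

    Significance requires BOTH the joint-significance criterion (b1, b2, b3
    each significant) and the bootstrap product-of-coefficients test.
    """
    cov_names = list(covariates or [])
    estimates = []
    for subject, arrs in _per_subject_arrays(data, [x, m1, m2, y] + cov_names):
        xv, m1v, m2v, yv = arrs[:4]
        cov = np.column_stack(arrs[4:]) if cov_names else None
        try:
            estimates.append(
                fit_three_path_subject(xv, m1v, m2v, yv, covariates=cov, subject=subject)
            )
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("subject %s dropped from mediation: %s", subject, err)
    if len(estimates) < 5:
        raise ValueError("fewer than 5 usable subjects")
    P = np.array([e.row() for e in estimates])
    V = np.array([e.var_row() for e in estimates])
    W = inverse_variance_weights(P, V) if weighted else None
    boot = bootstrap_paths(P, W, n_boot=n_boot, seed=seed, alpha=alpha,
                           names=THREE_PATH_NAMES)
    return _result_from_bootstrap(
        boot, alpha, len(estimates), seed, product_name="product",
        joint_names=["b1", "b2", "b3"], subject_estimates=estimates,
    )


# ---------------------------------------------------------------------------
# voxel-wise mediator search
# ---------------------------------------------------------------------------

def mediation_brain_search(
    subject_data: list,
    mode: str = "two_path",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    weighted: bool = True,
) -> dict:
    """Voxel-wise mediator search across subjects.

    ``subject_data`` is a list with one dict per subject:

    * ``x``, ``y`` — (n_trials,) vectors;
    * ``betas`` — (n_trials, n_voxels) per-trial voxel responses (voxels in
      a shared flattened order);
    * ``cov`` — optional (n_trials, q) covariates;
    * ``m_fixed`` — fixed mediator vector, required for the three-path modes.

    Modes: ``"two_path"`` (the voxel is the sole mediator), ``"search_m2"``
    (fixed first mediator, voxel is the second), ``"search_m1"`` (fixed
    second mediator, voxel is the first).  Returns flat per-voxel maps of
    path coefficients and bootstrap p-values plus a ``skipped`` mask for
    zero-variance voxels.  Single-voxel input reproduces the scalar pipeline
    exactly.
    """
    if mode not in {"two_path", "search_m2", "search_m1"}:
        raise ValueError(f"unknown mode {mode!r}")
    n_vox = subject_data[0]["betas"].shape[1]
    n_subj = len(subject_data)
    path_names = TWO_PATH_NAMES if mode == "two_path" else THREE_PATH_NAMES
    k = len(path_names)
    P = np.full((n_subj, n_vox, k), np.nan)
    V = np.full((n_subj, n_vox, k), np.nan)
    skipped = np.zeros(n_vox, dtype=bool)

    for s, sub in enumerate(subject_data):
        x = np.asarray(sub["x"], dtype=float)
        y = np.asarray(sub["y"], dtype=float)
        B = np.asarray(sub["betas"], dtype=float)
        cov = sub.get("cov")
        m_fixed = sub.get("m_fixed")
        var0 = B.var(axis=0)
        dead = var0 <= 1e-14
        skipped |= dead
        for v in range(n_vox):
            if dead[v]:
                continue
            try:
                if mode == "two_path":
                    e = fit_two_path_subject(x, B[:, v], y, covariates=cov)
                elif mode == "search_m2":
                    e = fit_three_path_subject(
                        x, m_fixed, B[:, v], y, covariates=cov
                    )
                else:  # search_m1
                    e = fit_three_path_subject(
                        x, B[:, v], m_fixed, y, covariates=cov
                    )
                P[s, v] = e.row()
                V[s, v] = e.var_row()
            except (np.linalg.LinAlgError, ValueError):
                skipped[v] = True

    ok = ~skipped & np.isfinite(P).all(axis=(0, 2))
    maps = {nm: np.full(n_vox, np.nan) for nm in path_names}
    pmaps = {f"p_{nm}": np.full(n_vox, np.nan) for nm in path_names}
    if ok.any():
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n_subj, np.full(n_subj, 1.0 / n_subj), size=n_boot)
        for j, nm in enumerate(path_names):
            E = P[:, ok, j]            # (n_subj, n_ok)
            WV = V[:, ok, j]
            if weighted:
                tau2 = np.maximum(0.0, E.var(axis=0, ddof=1) - WV.mean(axis=0))
                W = 1.0 / (WV + tau2)
            else:
                W = np.ones_like(E)
            stats_ = (counts @ (W * E)) / (counts @ W)   # (n_boot, n_ok)
            point = (W * E).sum(axis=0) / W.sum(axis=0)
            share = np.minimum(
                (stats_ <= 0).mean(axis=0), (stats_ >= 0).mean(axis=0)
            )
            p = np.clip(_expanded_tail_p(share, n_subj), 2.0 / n_boot, 1.0)
            maps[nm][ok] = point
            pmaps[f"p_{nm}"][ok] = p
    out = {**maps, **pmaps, "skipped": skipped, "names": path_names,
           "n_boot": n_boot, "seed": seed, "alpha": alpha}
    product = "ab" if mode == "two_path" else "product"
    sig = (pmaps[f"p_{product}"] < alpha)
    if mode != "two_path":
        for nm in ("b1", "b2", "b3"):
            sig &= pmaps[f"p_{nm}"] < alpha
    out["significant"] = np.where(np.isnan(pmaps[f"p_{product}"]), False, sig)
    return out
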
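"""Single-trial ("beta series") GLM estimation with collinearity screening.

One regressor per 12.5-s stimulation epoch plus a shared rating-period
regressor, both convolved with a canonical double-gamma HRF; nuisance
structure covers run intercept, linear drift, a discrete-cosine high-pass
set (180-s cutoff), optional spike indicator columns, and optional
user-supplied columns (e.g. movement parameters).  Per-trial variance
inflation factors quantify design-induced uncertainty; trials with
VIF > 2.5 are flagged for exclusion.  An image-wise Mahalanobis outlier
detector on slice-wise summary statistics supplies the spike indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "VIF_EXCLUSION_THRESHOLD",
    "NuisanceSpec",
    "DesignMatrix",
    "BetaSeries",
    "canonical_hrf",
    "build_single_trial_design",
    "estimate_single_trial_betas",
    "compute_trial_vifs",
    "detect_outlier_images",
]

VIF_EXCLUSION_THRESHOLD = 2.5
HIGHPASS_CUTOFF_S = 180.0

# canonical double-gamma HRF: response peaking at 6 s, undershoot peaking at
# 16 s with amplitude ratio 1/6, 32-s support
HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 1.0 / 6.0
HRF_SUPPORT_S = 32.0

STIM_DUR = 12.5
RATING_DUR = 11.0


def canonical_hrf(dt: float) -> np.ndarray:
    """Sampled canonical HRF kernel at resolution ``dt`` seconds, peak 1.

    Difference of two gamma densities (unit scale) whose modes sit at the
    response and undershoot peaks; value 0 at t = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_SUPPORT_S + dt / 2, dt)
    h = stats.gamma.pdf(t, HRF_PEAK_S + 1.0) - HRF_RATIO * stats.gamma.pdf(
        t, HRF_UNDERSHOOT_S + 1.0
    )
    return h / h.max()


def _convolved_regressor(onsets, durations, tr, n_volumes, dt=0.1) -> np.ndarray:
    hrf = canonical_hrf(dt)
    n_fine = int(np.ceil(n_volumes * tr / dt)) + 1
    fine = np.zeros(n_fine)
    for on, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        a, b = int(round(on / dt)), int(round((on + dur) / dt))
        if b > n_fine:
            raise ValueError("event extends past the end of the run")
        fine[a:b] = 1.0
    # dt scaling approximates the continuous convolution integral
    conv = np.convolve(fine, hrf)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[vol_idx]


def cosine_drift_basis(n_volumes: int, tr: float, cutoff: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine high-pass basis; floor(2*T/cutoff) columns."""
    T = n_volumes * tr
    k_max = int(np.floor(2.0 * T / cutoff))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes)) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class NuisanceSpec:
    """Which nuisance columns to include in a single-run design."""

    intercept: bool = True
    linear_drift: bool = True
    highpass_cutoff: float | None = HIGHPASS_CUTOFF_S
    spike_volumes: tuple = ()
    extra_columns: np.ndarray | None = None  # e.g. movement proxies, (T, q)
    extra_names: tuple = ()


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    trial_columns: list
    nuisance_columns: list
    column_names: list
    tr: float

    def __post_init__(self) -> None:
        norms = np.abs(self.matrix).sum(axis=0)
        if np.any(norms == 0):
            dead = [self.column_names[j] for j in np.flatnonzero(norms == 0)]
            raise ValueError(f"all-zero design columns: {dead}")

    @property
    def n_trials(self) -> int:
        return len(self.trial_columns)


@dataclass
class BetaSeries:
    """Per-trial amplitude estimates with design-collinearity diagnostics."""

    betas: np.ndarray          # (n_trials,) or (n_trials, n_targets)
    vif: np.ndarray            # (n_trials,)
    excluded: np.ndarray       # (n_trials,) bool; True iff vif > 2.5
    residual_variance: float | np.ndarray = np.nan
    all_coefficients: np.ndarray = field(default=None, repr=False)


def build_single_trial_design(
    run_events, tr: float, n_volumes: int, nuisance_spec: NuisanceSpec | None = None
) -> DesignMatrix:
    """Single-run design: one column per stimulation trial + nuisance block.

    ``run_events`` is a DataFrame with columns ``stim_onset``,
    ``stim_duration``, ``rating_onset``, ``rating_duration`` (one row per
    trial; see :func:`painpath.simulate.trial_timing`).  The fixation epochs
    are the implicit baseline.
    """
    spec = nuisance_spec or NuisanceSpec()
    ev = run_events.reset_index(drop=True)
    ends = ev["stim_onset"] + ev["stim_duration"]
    if (ev["stim_onset"].to_numpy()[1:] < ends.to_numpy()[:-1]).any():
        raise ValueError("overlapping trial stimulation epochs")
    if (ev["rating_onset"] + ev["rating_duration"]).max() > n_volumes * tr:
        raise ValueError("events extend past the end of the run")

    cols, names = [], []
    for i, row in ev.iterrows():
        cols.append(
            _convolved_regressor(row["stim_onset"], row["stim_duration"], tr, n_volumes)
        )
        names.append(f"trial_{i + 1:03d}")
    trial_columns = list(range(len(cols)))

    cols.append(
        _convolved_regressor(
            ev["rating_onset"].to_numpy(), ev["rating_duration"].to_numpy(), tr, n_volumes
        )
    )
    names.append("rating")

    if spec.intercept:
        cols.append(np.ones(n_volumes))
        names.append("intercept")
    if spec.linear_drift:
        drift = np.arange(n_volumes, dtype=float)
        cols.append(drift - drift.mean())
        names.append("drift")
    if spec.highpass_cutoff:
        dct = cosine_drift_basis(n_volumes, tr, spec.highpass_cutoff)
        for k in range(dct.shape[1]):
            cols.append(dct[:, k])
            names.append(f"cosine_{k + 1:02d}")
    for v in spec.spike_volumes:
        ind = np.zeros(n_volumes)
        ind[v] = 1.0
        cols.append(ind)
        names.append(f"spike_{v:04d}")
    if spec.extra_columns is not None:
        extra = np.atleast_2d(np.asarray(spec.extra_columns, dtype=float))
        if extra.shape[0] != n_volumes:
            extra = extra.T
        for q in range(extra.shape[1]):
            cols.append(extra[:, q])
            names.append(
                spec.extra_names[q] if q < len(spec.extra_names) else f"extra_{q + 1}"
            )

    X = np.column_stack(cols)
    nuisance_columns = list(range(len(trial_columns), X.shape[1]))
    return DesignMatrix(
        matrix=X, trial_columns=trial_columns, nuisance_columns=nuisance_columns,
        column_names=names, tr=tr,
    )


def estimate_single_trial_betas(series, design: DesignMatrix) -> BetaSeries:
    """OLS beta-series estimates; raises naming offending columns if rank-deficient."""
    y = np.asarray(series, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("series length does not match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = [design.column_names[j] for j in bad]
        raise np.linalg.LinAlgError(f"rank-deficient design; dependent columns: {names}")
    coef, res_ss, _, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = X.shape[0] - X.shape[1]
    if y.ndim == 1:
        rss = float(res_ss[0]) if res_ss.size else float(np.sum((y - X @ coef) ** 2))
        resid_var = rss / dof if dof > 0 else np.nan
    else:
        rss = np.sum((y - X @ coef) ** 2, axis=0)
        resid_var = rss / dof if dof > 0 else np.full(y.shape[1], np.nan)
    vif = compute_trial_vifs(design)
    return BetaSeries(
        betas=coef[design.trial_columns],
        vif=vif,
        excluded=vif > VIF_EXCLUSION_THRESHOLD,
        residual_variance=resid_var,
        all_coefficients=coef,
    )


def compute_trial_vifs(design: DesignMatrix) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j), regressing each trial column on all other columns.

    Perfect collinearity yields +inf (and exclusion downstream).
    """
    X = design.matrix
    vifs = np.empty(len(design.trial_columns))
    for k, j in enumerate(design.trial_columns):
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = np.sum((target - target.mean()) ** 2)
        if sst <= 0:
            vifs[k] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        vifs[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return np.maximum(vifs, 1.0)


def detect_outlier_images(series_4d: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Flag outlier volumes by Mahalanobis distance on slice-wise summaries.

    For each volume the feature vector concatenates the mean and standard
    deviation of every z-slice; squared Mahalanobis distances to the sample
    centroid are referred to a chi-square with one df per feature, and a
    volume is flagged only when its tail probability is significant under
    both Bonferroni and Benjamini-Hochberg correction (the more stringent
    combination).  A singular feature covariance triggers ridge shrinkage
    with a warning.
    """
    data = np.asarray(series_4d, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a (time, x, y, z) array")
    n_vols, _, _, n_slices = data.shape
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    means = data.mean(axis=(1, 2))          # (T, nz)
    sds = data.std(axis=(1, 2))
    feats = np.concatenate([means, sds], axis=1)  # (T, 2*nz)

    centered = feats - feats.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    p = feats.shape[1]
    # drop constant features (degenerate inputs) before inverting
    keep = np.diag(cov) > 1e-12
    if not keep.any():
        warnings.warn("all slice-wise features constant; no outliers detectable")
        return np.zeros(n_vols, dtype=bool)
    cov = cov[np.ix_(keep, keep)]
    centered = centered[:, keep]
    p = int(keep.sum())
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = None
    if cov_inv is None or np.linalg.cond(cov) > 1e10 or n_vols <= p:
        ridge = 1e-6 * np.trace(cov) / p
        warnings.warn("singular feature covariance; applying ridge shrinkage")
        cov_inv = np.linalg.inv(cov + ridge * np.eye(p))
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    pvals = stats.chi2.sf(d2, df=p)

    bonf = pvals < alpha / n_vols
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresh = alpha * (np.arange(1, n_vols + 1)) / n_vols
    below = ranked <= thresh
    fdr = np.zeros(n_vols, dtype=bool)
    if below.any():
        k_star = np.max(np.flatnonzero(below))
        fdr[order[: k_star + 1]] = True
    return bonf & fdr
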
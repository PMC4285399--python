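"""Replication-style validation studies over the synthetic generative model.

Each study generates many independent synthetic datasets under the default
study conditions (30 subjects, the 9-run design, default ground truth),
runs the corresponding analysis exactly as a user would, and reports an
empirical operating characteristic: type-I error of the indirect-effect
bootstrap under a null path, ground-truth recovery rates, replication of
the planted two-system dissociation, closed-loop FWER of the Monte-Carlo
cluster threshold, and planted-cluster recovery of the voxel-wise search.

These functions are shared by the test suite and the acceptance script so
that reported operating characteristics always come from a fresh run of the
full pipeline, never from stored numbers.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .clusters import _FACE_STRUCTURE, monte_carlo_cluster_threshold
from .design import generate_design
from .mediation import (
    mediation_brain_search,
    multilevel_mediation,
    multilevel_three_path,
)
from .params import GroundTruthParams, TEMP_CENTER_C
from .simulate import simulate_trial_responses, simulate_voxel_brain

__all__ = [
    "simulate_study",
    "type_i_error_study",
    "recovery_study",
    "dissociation_study",
    "fwer_closed_loop",
    "planted_search_study",
]


def _streams(seed: int, n: int) -> list:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_study(n_subjects: int, seed: int, params: GroundTruthParams | None = None):
    """One synthetic dataset under default study conditions, analysis-ready."""
    params = params or GroundTruthParams()
    s1, s2 = _streams(seed, 2)
    design = generate_design(n_subjects, seed=s1)
    ds = simulate_trial_responses(design, params, seed=s2)
    trials = ds.trials.copy()
    trials["temp_centered"] = trials["temp_c"] - TEMP_CENTER_C
    return trials, params


def type_i_error_study(
    n_replicates: int = 500,
    n_subjects: int = 30,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the indirect-effect bootstrap under a true null path.

    The regulation -> signature path is null by construction (the signature
    responds to temperature only), so the a*b test of the
    regulation -> signature -> pain model estimates the type-I error.
    """
    seeds = _streams(seed, 2 * n_replicates)
    rejections = 0
    for r in range(n_replicates):
        trials, _ = simulate_study(n_subjects, seeds[2 * r])
        res = multilevel_mediation(
            trials, x="reg_code", m="sig", y="rating",
            covariates=["temp_centered"],
            n_boot=n_boot, seed=seeds[2 * r + 1], alpha=alpha,
        )
        rejections += res.paths["ab"].p < alpha
    return {
        "rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
    }


def recovery_study(
    n_replicates: int = 50,
    n_subjects: int = 30,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Share of replicates recovering each generative path within 2 bootstrap SEs."""
    seeds = _streams(seed, 3 * n_replicates)
    params = GroundTruthParams()
    targets = {
        "temp_to_pain": params.temp_to_pain,
        "temp_to_sig": params.temp_to_sig,
        "sig_to_pain": params.sig_to_pain,
        "reg_to_m1": params.reg_to_m1,
        "m1_to_m2": params.m1_to_m2,
        "m2_to_pain": params.m2_to_pain,
    }
    hits = {k: 0 for k in targets}
    for r in range(n_replicates):
        trials, _ = simulate_study(n_subjects, seeds[3 * r], params)
        temp_med = multilevel_mediation(
            trials, x="temp_centered", m="sig", y="rating",
            covariates=["reg_code"], n_boot=n_boot, seed=seeds[3 * r + 1],
        )
        chain = multilevel_three_path(
            trials, x="reg_code", m1="m1", m2="m2", y="rating",
            covariates=["temp_centered", "sig"],
            n_boot=n_boot, seed=seeds[3 * r + 2],
        )
        estimates = {
            "temp_to_pain": temp_med.paths["c_prime"],
            "temp_to_sig": temp_med.paths["a"],
            "sig_to_pain": temp_med.paths["b"],
            "reg_to_m1": chain.paths["b1"],
            "m1_to_m2": chain.paths["b2"],
            "m2_to_pain": chain.paths["b3"],
        }
        for name, s in estimates.items():
            if abs(s.estimate - targets[name]) <= 2.0 * s.se:
                hits[name] += 1
    return {
        "rates": {k: v / n_replicates for k, v in hits.items()},
        "min_rate": min(hits.values()) / n_replicates,
        "pooled_rate": sum(hits.values()) / (len(hits) * n_replicates),
        "n_replicates": n_replicates,
    }


def dissociation_study(
    n_replicates: int = 50,
    n_subjects: int = 30,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Replication rate of the planted two-system dissociation.

    A replicate counts as replicating when (1) temperature -> signature ->
    pain mediation is significant, (2) regulation -> signature -> pain is
    not, (3) the regulation -> m1 -> m2 -> pain three-path model passes both
    the joint-significance and bootstrap product criteria, and (4) the
    reversed chain (m2 before m1) does not.
    """
    seeds = _streams(seed, 5 * n_replicates)
    counts = {"temp_sig": 0, "reg_sig_null": 0, "chain": 0, "reversed_null": 0,
              "all": 0}
    for r in range(n_replicates):
        trials, _ = simulate_study(n_subjects, seeds[5 * r])
        temp_med = multilevel_mediation(
            trials, x="temp_centered", m="sig", y="rating",
            covariates=["reg_code"], n_boot=n_boot, seed=seeds[5 * r + 1],
            alpha=alpha,
        )
        reg_med = multilevel_mediation(
            trials, x="reg_code", m="sig", y="rating",
            covariates=["temp_centered"], n_boot=n_boot,
            seed=seeds[5 * r + 2], alpha=alpha,
        )
        chain = multilevel_three_path(
            trials, x="reg_code", m1="m1", m2="m2", y="rating",
            covariates=["temp_centered", "sig"], n_boot=n_boot,
            seed=seeds[5 * r + 3], alpha=alpha,
        )
        rev = multilevel_three_path(
            trials, x="reg_code", m1="m2", m2="m1", y="rating",
            covariates=["temp_centered", "sig"], n_boot=n_boot,
            seed=seeds[5 * r + 4], alpha=alpha,
        )
        ok = {
            "temp_sig": temp_med.significant,
            "reg_sig_null": not reg_med.significant,
            "chain": chain.significant,
            "reversed_null": not rev.significant,
        }
        for k, v in ok.items():
            counts[k] += v
        counts["all"] += all(ok.values())
    return {
        "rates": {k: v / n_replicates for k, v in counts.items()},
        "rate_all": counts["all"] / n_replicates,
        "n_replicates": n_replicates,
    }


def fwer_closed_loop(
    mask_shape=(20, 20, 20),
    fwhm_mm: float = 6.0,
    primary_p: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 2000,
    n_fresh: int = 500,
    seed: int = 0,
    voxel_size_mm: float = 3.0,
) -> dict:
    """Empirical FWER of the Monte-Carlo extent threshold on fresh null fields."""
    from .clusters import _smooth_null_field

    s1, s2 = _streams(seed, 2)
    mask = np.ones(mask_shape, dtype=bool)
    thr = monte_carlo_cluster_threshold(
        mask, fwhm_mm=fwhm_mm, primary_p=primary_p, alpha_fwer=alpha,
        n_iter=n_iter, seed=s1, voxel_size_mm=voxel_size_mm,
    )
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    z_crit = stats.norm.isf(primary_p / 2.0)
    rng = np.random.default_rng(s2)
    false_positives = 0
    for _ in range(n_fresh):
        field = _smooth_null_field(mask_shape, sigma_vox, rng)
        field = field / field.std()
        lab, n_lab = ndimage.label(np.abs(field) > z_crit, structure=_FACE_STRUCTURE)
        if n_lab and np.bincount(lab.ravel())[1:].max() >= thr.k_min:
            false_positives += 1
    return {
        "fwer": false_positives / n_fresh,
        "k_min": int(thr.k_min),
        "n_fresh": n_fresh,
        "alpha": alpha,
    }


def planted_search_study(
    n_subjects: int = 30,
    grid_shape=(12, 12, 12),
    n_boot: int = 2000,
    primary_p: float = 0.005,
    n_iter: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Dice overlap of the voxel-wise second-mediator search with the truth.

    Simulates per-subject voxel brains sharing the planted cluster layout,
    searches for the second mediator of the regulation -> pain relationship
    with the true m1 scalar fixed, applies Monte-Carlo cluster-extent
    correction, and compares surviving voxels with the planted m2 cluster.
    """
    seeds = _streams(seed, n_subjects + 3)
    design = generate_design(n_subjects, seed=seeds[-1])
    params = GroundTruthParams()
    subject_data, brain = [], None
    for i, (subject, d) in enumerate(design.groupby("subject")):
        b, _, ds = simulate_voxel_brain(d, params, grid_shape=grid_shape,
                                        seed=seeds[i])
        brain = b
        subject_data.append(
            {
                "x": ds.trials["reg_code"].to_numpy(float),
                "y": ds.trials["rating"].to_numpy(float),
                "betas": b.per_trial_betas[:, b.mask],
                "cov": np.column_stack(
                    [ds.trials["temp_c"].to_numpy(float) - TEMP_CENTER_C,
                     ds.sig_response]
                ),
                "m_fixed": ds.m1,
            }
        )
    res = mediation_brain_search(
        subject_data, mode="search_m2", n_boot=n_boot, seed=seeds[-2],
        alpha=alpha,
    )
    thr = monte_carlo_cluster_threshold(
        brain.mask, fwhm_mm=0.0, primary_p=primary_p, alpha_fwer=alpha,
        n_iter=n_iter, seed=seeds[-3], voxel_size_mm=brain.voxel_size,
    )
    # cluster-forming threshold on the product-of-coefficients map; the
    # joint-significance criterion applies at the conventional level
    sig_vol = np.zeros(brain.grid_shape, dtype=bool)
    sig_vol[brain.mask] = (
        (res["p_product"] < primary_p) & (res["p_b1"] < alpha)
        & (res["p_b2"] < alpha) & (res["p_b3"] < alpha)
    )
    lab, n_lab = ndimage.label(sig_vol, structure=_FACE_STRUCTURE)
    surviving = np.zeros_like(sig_vol)
    for cid in range(1, n_lab + 1):
        vox = lab == cid
        if vox.sum() >= thr.k_min:
            surviving |= vox
    truth = brain.cluster_mask(brain.M2)
    denom = surviving.sum() + truth.sum()
    dice = 2.0 * (surviving & truth).sum() / denom if denom else 0.0
    return {
        "dice": float(dice),
        "k_min": int(thr.k_min),
        "n_significant": int(surviving.sum()),
        "n_true": int(truth.sum()),
    }
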
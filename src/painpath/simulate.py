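"""Simulation of trial-level responses, desk-scale voxel brains, and BOLD series.

``simulate_trial_responses`` draws subject-level random effects around the
population paths and generates, per trial:

* ``sig``   — signature-like scalar response driven by temperature only,
* ``m1``    — first mediator driven by the regulation code only,
* ``m2``    — second mediator driven by m1,
* ``rating``— additive combination of direct temperature and regulation
  effects, the signature response, and m2, plus noise, clipped to [0, 100],
* ``decision`` — 1 iff rating exceeds the decision threshold.

``simulate_voxel_brain`` embeds those scalar series in a small volumetric
grid with three disjoint planted clusters (signature / m1 / m2) on a noisy
background, together with a signature weight map supported on the signature
cluster, enabling voxel-wise mediator searches with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import GroundTruthParams, TEMP_CENTER_C

__all__ = [
    "TrialDataset",
    "SyntheticBrain",
    "simulate_trial_responses",
    "simulate_voxel_brain",
    "simulate_timeseries",
]

# trial timing (seconds): stimulation, pre-rating jitter range, rating epoch,
# inter-trial-interval jitter range, initial fixation
STIM_DUR = 12.5
PRE_RATING_RANGE = (4.5, 8.5)
RATING_DUR = 11.0
ITI_RANGE = (5.0, 9.0)
INITIAL_FIXATION = 18.0

_RANDOM_PATHS = [
    "rating_intercept", "temp_to_pain", "reg_to_pain_direct",
    "sig_intercept", "temp_to_sig", "sig_to_pain",
    "reg_to_m1", "m1_to_m2", "m2_to_pain",
]


@dataclass
class TrialDataset:
    """Trial table augmented with simulated responses plus its generating truth.

    ``trials`` carries one row per trial with columns ``sig``, ``m1``, ``m2``,
    ``rating``, ``decision`` filled in.  ``subject_effects`` records the
    realized per-subject path coefficients (useful for debugging recovery).
    """

    trials: pd.DataFrame
    truth: GroundTruthParams
    subject_effects: pd.DataFrame

    @property
    def sig_response(self) -> np.ndarray:
        return self.trials["sig"].to_numpy()

    @property
    def m1(self) -> np.ndarray:
        return self.trials["m1"].to_numpy()

    @property
    def m2(self) -> np.ndarray:
        return self.trials["m2"].to_numpy()


@dataclass
class SyntheticBrain:
    """Desk-scale stand-in for a whole-brain search space.

    ``cluster_assignments`` labels voxels 1 = signature cluster, 2 = m1
    cluster, 3 = m2 cluster, 0 = in-mask background; labels are disjoint and
    lie inside ``mask``.  ``per_trial_betas`` has shape (n_trials, *grid).
    """

    grid_shape: tuple
    voxel_size: float
    mask: np.ndarray
    cluster_assignments: np.ndarray
    per_trial_betas: np.ndarray
    affine: np.ndarray

    SIGNATURE, M1, M2 = 1, 2, 3

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.cluster_assignments == label


def _draw_subject_effects(params: GroundTruthParams, subjects, rng) -> pd.DataFrame:
    rows = {}
    for s in subjects:
        eff = {}
        for name in _RANDOM_PATHS:
            pop = getattr(params, name)
            sd = params.between_subject_sd.get(name, 0.0)
            eff[name] = rng.normal(pop, sd) if sd > 0 else pop
        rows[s] = eff
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject")


def simulate_trial_responses(
    design: pd.DataFrame, params: GroundTruthParams, seed: int
) -> TrialDataset:
    """Simulate sig/m1/m2/rating/decision for every trial of ``design``."""
    for name, sd in {**params.between_subject_sd, **params.residual_sd}.items():
        if sd < 0:
            raise ValueError(f"negative SD for {name!r}")
    rng = np.random.default_rng(seed)
    trials = design.copy().reset_index(drop=True)
    subjects = trials["subject"].unique()
    effects = _draw_subject_effects(params, subjects, rng)
    res = params.residual_sd

    sig = np.empty(len(trials))
    m1 = np.empty(len(trials))
    m2 = np.empty(len(trials))
    rating = np.empty(len(trials))
    for s in subjects:
        idx = np.flatnonzero(trials["subject"].to_numpy() == s)
        e = effects.loc[s]
        n = idx.size
        temp_c = trials["temp_c"].to_numpy()[idx] - TEMP_CENTER_C
        reg = trials["reg_code"].to_numpy()[idx].astype(float)
        sig_s = (
            e["sig_intercept"] + e["temp_to_sig"] * temp_c
            + rng.normal(0.0, res["sig"], n)
        )
        m1_s = e["reg_to_m1"] * reg + rng.normal(0.0, res["m1"], n)
        m2_s = e["m1_to_m2"] * m1_s + rng.normal(0.0, res["m2"], n)
        rating_s = (
            e["rating_intercept"]
            + e["temp_to_pain"] * temp_c
            + e["reg_to_pain_direct"] * reg
            + e["sig_to_pain"] * (sig_s - e["sig_intercept"])
            + e["m2_to_pain"] * m2_s
            + rng.normal(0.0, res["rating"], n)
        )
        sig[idx], m1[idx], m2[idx] = sig_s, m1_s, m2_s
        rating[idx] = np.clip(rating_s, 0.0, 100.0)

    trials["sig"] = sig
    trials["m1"] = m1
    trials["m2"] = m2
    trials["rating"] = rating
    trials["decision"] = (rating > params.decision_threshold).astype(int)
    return TrialDataset(trials=trials, truth=params, subject_effects=effects)


# ---------------------------------------------------------------------------
# volumetric brain
# ---------------------------------------------------------------------------

def _place_clusters(grid_shape, rng) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal mask with three disjoint cubic clusters inside it."""
    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    c = (np.array(grid_shape) - 1) / 2.0
    r = np.array(grid_shape) / 2.0
    mask = ((ii - c[0]) / r[0]) ** 2 + ((jj - c[1]) / r[1]) ** 2 + (
        (kk - c[2]) / r[2]
    ) ** 2 <= 1.0

    labels = np.zeros(grid_shape, dtype=int)
    side = max(2, min(grid_shape) // 5)
    # three well-separated anchor corners near the mask center plane
    anchors = [
        (int(c[0] - side - 1), int(c[1] - side - 1), int(c[2])),
        (int(c[0] + 1), int(c[1] + 1), int(c[2])),
        (int(c[0] - side - 1), int(c[1] + 1), int(c[2] - side - 1)),
    ]
    for label, (ax, ay, az) in zip((1, 2, 3), anchors):
        block = np.s_[ax: ax + side, ay: ay + side, az: az + side]
        if not mask[block].all():
            raise ValueError("grid too small to place disjoint clusters in mask")
        if (labels[block] != 0).any():
            raise ValueError("planted clusters overlap")
        labels[block] = label
    labels[~mask] = 0
    return mask, labels


def simulate_voxel_brain(
    design: pd.DataFrame,
    params: GroundTruthParams,
    grid_shape=(16, 16, 16),
    seed: int = 0,
    voxel_size: float = 3.0,
    voxel_noise_sd: float = 1.0,
):
    """Simulate per-trial beta volumes with planted signature/m1/m2 clusters.

    Returns ``(brain, signature, dataset)`` where ``signature`` is a
    :class:`painpath.patterns.SignaturePattern` whose weights are the
    signature-cluster loadings scaled so that the noise-free pattern response
    of a trial volume equals that trial's scalar ``sig`` value exactly.
    """
    from .patterns import SignaturePattern

    if max(grid_shape) > 30:
        raise ValueError("grid_shape is meant to stay desk-scale (<= 30 per axis)")
    rng = np.random.default_rng(seed)
    dataset = simulate_trial_responses(design, params, seed=int(rng.integers(2**31)))
    mask, labels = _place_clusters(grid_shape, rng)
    n_trials = len(dataset.trials)

    betas = np.zeros((n_trials,) + tuple(grid_shape))
    betas[:, mask] = rng.normal(0.0, voxel_noise_sd, (n_trials, int(mask.sum())))
    loadings = {}
    for label, series in (
        (SyntheticBrain.SIGNATURE, dataset.sig_response),
        (SyntheticBrain.M1, dataset.m1),
        (SyntheticBrain.M2, dataset.m2),
    ):
        vox = labels == label
        load = rng.normal(1.0, 0.2, int(vox.sum()))
        loadings[label] = load
        betas[:, vox] += np.outer(series, load)

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    brain = SyntheticBrain(
        grid_shape=tuple(grid_shape),
        voxel_size=voxel_size,
        mask=mask,
        cluster_assignments=labels,
        per_trial_betas=betas,
        affine=affine,
    )

    sig_vox = labels == SyntheticBrain.SIGNATURE
    load = loadings[SyntheticBrain.SIGNATURE]
    weights = np.zeros(grid_shape)
    weights[sig_vox] = load / np.dot(load, load)  # w.(sig*load) == sig
    signature = SignaturePattern(
        weights=weights, mask=sig_vox, affine=affine, region_labels=None
    )
    return brain, signature, dataset


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def trial_timing(n_trials: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw jittered stimulus/rating onsets for one run (seconds)."""
    rows = []
    t = INITIAL_FIXATION
    for i in range(n_trials):
        stim_on = t
        pre = rng.uniform(*PRE_RATING_RANGE)
        rating_on = stim_on + STIM_DUR + pre
        iti = rng.uniform(*ITI_RANGE)
        rows.append(
            {"trial": i, "stim_onset": stim_on, "stim_duration": STIM_DUR,
             "rating_onset": rating_on, "rating_duration": RATING_DUR}
        )
        t = rating_on + RATING_DUR + iti
    return pd.DataFrame(rows)


def simulate_timeseries(
    design_run: pd.DataFrame,
    amplitudes: np.ndarray,
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    outlier_spec: dict | None = None,
    tr: float = 2.0,
    seed: int = 0,
    events: pd.DataFrame | None = None,
    n_volumes: int | None = None,
):
    """Simulate a single-run BOLD-like series from per-trial amplitudes.

    The series is the sum of per-trial HRF-convolved stimulation boxcars
    scaled by ``amplitudes``, a linear drift of ``drift_slope`` units per
    volume, i.i.d. Gaussian noise, and optional spike volumes injected at
    ``outlier_spec = {volume_index: magnitude}``.

    Returns ``(series, events)``; pass ``events`` back in to reuse a timing
    realization (e.g. to build the matching design matrix).
    """
    from .glm import canonical_hrf

    rng = np.random.default_rng(seed)
    n_trials = len(design_run)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape[0] != n_trials:
        raise ValueError("one amplitude per trial required")
    if events is None:
        events = trial_timing(n_trials, rng)

    end_time = float(events["rating_onset"].iloc[-1] + RATING_DUR + ITI_RANGE[1])
    if n_volumes is None:
        n_volumes = int(np.ceil(end_time / tr)) + 2
    if events["stim_onset"].iloc[-1] + STIM_DUR > n_volumes * tr:
        raise ValueError("trial onsets exceed series length")

    dt = 0.1
    n_fine = int(np.ceil(n_volumes * tr / dt)) + 1
    hrf = canonical_hrf(dt)
    fine = np.zeros(n_fine)
    series = np.zeros(n_volumes)
    for i, amp in enumerate(amplitudes):
        fine[:] = 0.0
        on = int(round(events["stim_onset"].iloc[i] / dt))
        off = int(round((events["stim_onset"].iloc[i] + STIM_DUR) / dt))
        fine[on:off] = 1.0
        conv = np.convolve(fine, hrf)[:n_fine] * dt
        vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
        series += amp * conv[vol_idx]
    series += drift_slope * np.arange(n_volumes)
    if noise_sd > 0:
        series += rng.normal(0.0, noise_sd, n_volumes)
    if outlier_spec:
        for vol, magnitude in outlier_spec.items():
            if not 0 <= vol < n_volumes:
                raise ValueError(f"spike volume {vol} outside series")
            series[vol] += magnitude
    return series, events
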
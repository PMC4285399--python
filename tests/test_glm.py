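"""Single-trial GLM: HRF shape, design construction, beta estimation against
a pseudoinverse oracle, VIF computation against a brute-force regression
oracle, high-pass behavior, and outlier-image detection."""

import numpy as np
import pytest
from scipy import linalg

from painpath import (
    DesignMatrix,
    NuisanceSpec,
    build_single_trial_design,
    canonical_hrf,
    compute_trial_vifs,
    detect_outlier_images,
    estimate_single_trial_betas,
    generate_design,
    simulate_timeseries,
)
from painpath.glm import cosine_drift_basis


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------

def test_hrf_shape():
    h = canonical_hrf(0.1)
    t = np.arange(len(h)) * 0.1
    assert h[0] == 0.0
    assert abs(t[np.argmax(h)] - 6.0) <= 0.5
    assert h.max() == pytest.approx(1.0)
    assert h.sum() > 0  # positive response dominates the undershoot
    # undershoot present and bounded by the 1/6 ratio
    assert -1 / 6 - 0.01 < h.min() < 0


def test_hrf_invalid_dt():
    with pytest.raises(ValueError):
        canonical_hrf(0.0)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

N_VOL = 220  # 440 s, enough for an 11-trial passive run


@pytest.fixture(scope="module")
def run_events():
    design = generate_design(1, seed=4)
    run = design[design["run"] == 1]
    series, events = simulate_timeseries(
        run, np.zeros(len(run)), seed=0, n_volumes=N_VOL
    )
    assert len(series) == N_VOL
    return events


def test_design_columns_and_rank(run_events):
    dm = build_single_trial_design(run_events, tr=2.0, n_volumes=N_VOL)
    assert len(dm.trial_columns) == len(run_events)
    assert dm.matrix.shape[0] == N_VOL
    assert np.linalg.matrix_rank(dm.matrix) == dm.matrix.shape[1]
    # 180-s high-pass on a 440-s run: floor(2*440/180) = 4 cosine terms
    assert sum(n.startswith("cosine") for n in dm.column_names) == 4
    assert "rating" in dm.column_names
    assert "intercept" in dm.column_names


def test_cosine_basis_count():
    assert cosine_drift_basis(200, 2.0).shape == (200, 4)
    assert cosine_drift_basis(45, 2.0).shape == (45, 1)


def test_overlapping_epochs_rejected(run_events):
    bad = run_events.copy()
    bad.loc[1, "stim_onset"] = bad.loc[0, "stim_onset"] + 1.0
    bad = bad.sort_values("stim_onset").reset_index(drop=True)
    with pytest.raises(ValueError, match="overlap"):
        build_single_trial_design(bad, tr=2.0, n_volumes=300)


def test_spike_and_extra_columns(run_events):
    extra = np.random.default_rng(0).normal(size=(N_VOL, 2))
    dm = build_single_trial_design(
        run_events, tr=2.0, n_volumes=N_VOL,
        nuisance_spec=NuisanceSpec(spike_volumes=(7,), extra_columns=extra,
                                   extra_names=("mov_x", "mov_y")),
    )
    j = dm.column_names.index("spike_0007")
    assert dm.matrix[7, j] == 1.0 and dm.matrix[:, j].sum() == 1.0
    assert "mov_x" in dm.column_names


# ---------------------------------------------------------------------------
# beta estimation
# ---------------------------------------------------------------------------

def test_beta_recovery_noise_free(run_events, rng):
    dm = build_single_trial_design(run_events, tr=2.0, n_volumes=N_VOL)
    amps = rng.normal(2.0, 1.0, len(dm.trial_columns))
    series = dm.matrix[:, dm.trial_columns] @ amps
    bs = estimate_single_trial_betas(series, dm)
    np.testing.assert_allclose(bs.betas, amps, atol=1e-8)


def test_constant_shift_absorbed_by_intercept(run_events, rng):
    dm = build_single_trial_design(run_events, tr=2.0, n_volumes=N_VOL)
    amps = rng.normal(0.0, 1.0, len(dm.trial_columns))
    series = dm.matrix[:, dm.trial_columns] @ amps
    b0 = estimate_single_trial_betas(series, dm).betas
    b1 = estimate_single_trial_betas(series + 17.3, dm).betas
    np.testing.assert_allclose(b0, b1, atol=1e-9)


def test_betas_match_pseudoinverse_oracle(rng):
    X = rng.normal(size=(50, 10))
    y = rng.normal(size=50)
    dm = DesignMatrix(
        matrix=X, trial_columns=list(range(6)), nuisance_columns=list(range(6, 10)),
        column_names=[f"c{i}" for i in range(10)], tr=2.0,
    )
    bs = estimate_single_trial_betas(y, dm)
    oracle = linalg.pinv(X) @ y
    assert np.max(np.abs(bs.betas - oracle[:6])) < 1e-10


def test_rank_deficient_design_names_columns(rng):
    X = rng.normal(size=(40, 4))
    X[:, 3] = X[:, 0]
    dm = DesignMatrix(
        matrix=X, trial_columns=[0, 1], nuisance_columns=[2, 3],
        column_names=["t1", "t2", "n1", "n2"], tr=2.0,
    )
    with pytest.raises(np.linalg.LinAlgError, match="t1|n2"):
        estimate_single_trial_betas(rng.normal(size=40), dm)


def test_beta_recovery_invariant_random_designs(rng):
    """Noise-free recovery across 100 random designs, max error < 1e-6."""
    worst = 0.0
    for _ in range(100):
        n, k = 60, 8
        X = rng.normal(size=(n, k))
        amps = rng.normal(size=4)
        nuis = rng.normal(size=k - 4)
        y = X @ np.concatenate([amps, nuis])
        dm = DesignMatrix(
            matrix=X, trial_columns=[0, 1, 2, 3], nuisance_columns=[4, 5, 6, 7],
            column_names=[f"c{i}" for i in range(8)], tr=1.0,
        )
        bs = estimate_single_trial_betas(y, dm)
        worst = max(worst, np.max(np.abs(bs.betas - amps)))
    assert worst < 1e-6


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def _vif_oracle(X, trial_columns):
    out = []
    for j in trial_columns:
        others = np.delete(X, j, axis=1)
        coef = linalg.pinv(others) @ X[:, j]
        resid = X[:, j] - others @ coef
        sst = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1 - resid @ resid / sst
        out.append(np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2))
    return np.array(out)


def test_vif_orthogonal_columns():
    X = np.eye(8)[:, :4] * 2.0
    dm = DesignMatrix(matrix=X, trial_columns=[0, 1, 2], nuisance_columns=[3],
                      column_names=list("abcd"), tr=1.0)
    # orthogonal columns: no linear dependence, VIF pinned at its floor of 1
    assert np.allclose(compute_trial_vifs(dm), 1.0)


def test_vif_duplicate_is_infinite_and_excluded(rng):
    X = rng.normal(size=(30, 3))
    X = np.column_stack([X, X[:, 0]])
    dm = DesignMatrix(matrix=X, trial_columns=[0, 1], nuisance_columns=[2, 3],
                      column_names=list("abcd"), tr=1.0)
    vifs = compute_trial_vifs(dm)
    assert np.isinf(vifs[0])
    bs_excluded = vifs > 2.5
    assert bs_excluded[0] and not bs_excluded[1]


def test_vif_constructed_r2():
    """A trial column with R^2 = 0.75 against the rest has VIF exactly 4."""
    n = 64
    g = np.cos(2 * np.pi * np.arange(n) / n)
    h = np.sin(2 * np.pi * np.arange(n) / n)
    g, h = g - g.mean(), h - h.mean()
    g, h = g / np.linalg.norm(g), h / np.linalg.norm(h)
    col = np.sqrt(3) * g + 1.0 * h  # R^2 = 3/4 against span{1, g}
    X = np.column_stack([col, np.ones(n), g])
    dm = DesignMatrix(matrix=X, trial_columns=[0], nuisance_columns=[1, 2],
                      column_names=list("tig"), tr=1.0)
    assert compute_trial_vifs(dm)[0] == pytest.approx(4.0, abs=1e-8)


def test_vif_matches_oracle_random_designs(rng):
    for _ in range(20):
        X = rng.normal(size=(50, 9))
        # induce some collinearity
        X[:, 0] += 0.8 * X[:, 5]
        dm = DesignMatrix(
            matrix=X, trial_columns=[0, 1, 2, 3], nuisance_columns=[4, 5, 6, 7, 8],
            column_names=[f"c{i}" for i in range(9)], tr=1.0,
        )
        got = compute_trial_vifs(dm)
        want = np.maximum(_vif_oracle(X, [0, 1, 2, 3]), 1.0)
        np.testing.assert_allclose(got, want, rtol=1e-8)


def test_vif_monotone_in_trial_overlap():
    """Shrinking the gap between two trials never decreases either VIF."""
    import pandas as pd

    prev = None
    for gap in (40.0, 25.0, 15.0, 8.0, 2.0):
        events = pd.DataFrame(
            {
                "trial": [0, 1],
                "stim_onset": [20.0, 20.0 + 12.5 + gap],
                "stim_duration": [12.5, 12.5],
                "rating_onset": [150.0, 170.0],
                "rating_duration": [11.0, 11.0],
            }
        )
        dm = build_single_trial_design(events, tr=2.0, n_volumes=100)
        vifs = compute_trial_vifs(dm)
        if prev is not None:
            assert np.all(vifs >= prev - 1e-9)
        prev = vifs


def test_highpass_removes_slow_sinusoid(run_events, rng):
    """A slow drift (period > 180 s) barely moves the trial betas."""
    dm = build_single_trial_design(run_events, tr=2.0, n_volumes=N_VOL)
    amps = rng.normal(1.0, 0.5, len(dm.trial_columns))
    series = dm.matrix[:, dm.trial_columns] @ amps
    t = np.arange(N_VOL) * 2.0
    amplitude = 5.0
    drifted = series + amplitude * np.sin(2 * np.pi * t / 400.0 + 0.7)
    b0 = estimate_single_trial_betas(series, dm).betas
    b1 = estimate_single_trial_betas(drifted, dm).betas
    assert np.max(np.abs(b1 - b0)) < 0.01 * amplitude


# ---------------------------------------------------------------------------
# outlier images
# ---------------------------------------------------------------------------

def test_outlier_null_rate(rng):
    vols = rng.standard_normal((200, 6, 6, 8))
    assert detect_outlier_images(vols).sum() <= 1


def test_outlier_scaled_volume_flagged(rng):
    vols = rng.standard_normal((150, 6, 6, 8))
    vols[77] *= 10.0
    flags = detect_outlier_images(vols)
    assert flags[77]


def test_outlier_degenerate_identical_volumes():
    vols = np.ones((50, 4, 4, 4))
    with pytest.warns(UserWarning):
        flags = detect_outlier_images(vols)
    assert flags.sum() == 0
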
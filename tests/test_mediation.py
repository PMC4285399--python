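"""Mediation path systems: algebraic identities, product-variance estimators
against Monte-Carlo oracles, bootstrap behavior, three-path criteria, and
the voxel-wise search's consistency with the scalar pipeline."""

import numpy as np
import pandas as pd
import pytest

from painpath import (
    bootstrap_paths,
    delta_variance_product3,
    fit_three_path_subject,
    fit_two_path_subject,
    mediation_brain_search,
    multilevel_mediation,
    multilevel_three_path,
    sobel_variance,
)


# ---------------------------------------------------------------------------
# first-level fits
# ---------------------------------------------------------------------------

def test_full_mediation_chain_identity(rng):
    """Noise-free chain x -> m -> y (y = m) gives a = b = c = 1, c' = 0.

    An infinitesimal jitter keeps m identifiable from x; exact duplication
    is rank-deficient and raises (checked below).
    """
    x = rng.normal(size=50)
    m = x + 1e-7 * rng.normal(size=50)
    e = fit_two_path_subject(x, m, m.copy())
    assert e.a == pytest.approx(1.0, abs=1e-6)
    assert e.b == pytest.approx(1.0, abs=1e-6)
    assert e.c == pytest.approx(1.0, abs=1e-6)
    assert e.c_prime == pytest.approx(0.0, abs=1e-6)
    assert e.ab == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(np.linalg.LinAlgError):
        fit_two_path_subject(x, x.copy(), x.copy())


def test_c_minus_cprime_equals_ab(rng):
    """Single-level OLS identity c - c' = a*b on arbitrary data."""
    for _ in range(20):
        n = 40
        x = rng.normal(size=n)
        m = 0.7 * x + rng.normal(size=n)
        y = 0.4 * m - 0.2 * x + rng.normal(size=n)
        e = fit_two_path_subject(x, m, y)
        assert e.c - e.c_prime == pytest.approx(e.ab, abs=1e-8)


def test_null_a_path_within_2se(rng):
    n = 10_000
    x = rng.normal(size=n)
    m = rng.normal(size=n)  # independent of x
    y = 0.5 * m + rng.normal(size=n)
    e = fit_two_path_subject(x, m, y)
    assert abs(e.a) < 2 * np.sqrt(e.var_a)


def test_collinear_covariate_raises(rng):
    x = rng.normal(size=30)
    with pytest.raises(np.linalg.LinAlgError):
        fit_two_path_subject(x, rng.normal(size=30), rng.normal(size=30),
                             covariates=x[:, None] * 2.0)


def test_three_path_noise_free_unit_chain(rng):
    """Unit-slope chain x -> m1 -> m2 -> y with exactly orthogonal innovations."""
    n = 60
    x = rng.normal(size=n)

    def orthogonalize(v, basis):
        B = np.column_stack(basis)
        return v - B @ np.linalg.lstsq(B, v, rcond=None)[0]

    u1 = orthogonalize(rng.normal(size=n), [np.ones(n), x])
    m1 = x + u1
    u2 = orthogonalize(rng.normal(size=n), [np.ones(n), x, m1])
    m2 = m1 + u2
    e = fit_three_path_subject(x, m1, m2, m2.copy())
    assert e.b1 == pytest.approx(1.0, abs=1e-6)
    assert e.b2 == pytest.approx(1.0, abs=1e-6)
    assert e.b3 == pytest.approx(1.0, abs=1e-6)
    assert e.product == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# product-variance estimators
# ---------------------------------------------------------------------------

def test_sobel_limiting_and_arithmetic():
    assert sobel_variance(0.0, 0.0, 0.01, 0.04) == pytest.approx(0.0004)
    assert sobel_variance(0.5, 0.3, 0.01, 0.04) == pytest.approx(0.0113)
    assert sobel_variance(0.5, 0.3, 0.01, 0.04, second_order=False) == (
        pytest.approx(0.0109)
    )
    with pytest.raises(ValueError):
        sobel_variance(0.1, 0.1, -0.01, 0.01)


def test_sobel_matches_monte_carlo(rng):
    """Second-order form is exact for independent normal estimates."""
    a, b, va, vb = 0.5, 0.3, 0.01, 0.04
    draws_a = rng.normal(a, np.sqrt(va), 1_000_000)
    draws_b = rng.normal(b, np.sqrt(vb), 1_000_000)
    mc = np.var(draws_a * draws_b)
    assert sobel_variance(a, b, va, vb) == pytest.approx(mc, rel=0.03)


def test_delta3_substitutions():
    assert delta_variance_product3(0.0, 2.0, 3.0, 0.5, 1.0, 1.0) == (
        pytest.approx((2.0 * 3.0) ** 2 * 0.5)
    )
    v = 0.04
    assert delta_variance_product3(1, 1, 1, v, v, v) == pytest.approx(3 * v)


def test_delta3_matches_monte_carlo(rng):
    """First-order form matches simulation at moderate coefficients of variation."""
    b = (1.0, 0.8, -1.2)
    v = (0.01, 0.008, 0.02)
    draws = [rng.normal(bi, np.sqrt(vi), 1_000_000) for bi, vi in zip(b, v)]
    mc = np.var(draws[0] * draws[1] * draws[2])
    assert delta_variance_product3(*b, *v) == pytest.approx(mc, rel=0.10)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_constant_column_floored():
    P = np.ones((12, 1))
    with pytest.warns(UserWarning, match="degenerate"):
        res = bootstrap_paths(P, n_boot=2000, seed=1)
    assert res["p"][0] == pytest.approx(2 / 2000)


def test_bootstrap_symmetric_column_near_one():
    P = np.array([1.0, -1.0] * 10)[:, None]
    res = bootstrap_paths(P, n_boot=4000, seed=2)
    assert res["p"][0] > 0.6


def test_bootstrap_reproducible_and_order_insensitive(rng):
    P = rng.normal(0.2, 1.0, size=(25, 3))
    r1 = bootstrap_paths(P, n_boot=4000, seed=9)
    r2 = bootstrap_paths(P, n_boot=4000, seed=9)
    np.testing.assert_array_equal(r1["p"], r2["p"])
    np.testing.assert_array_equal(r1["ci_low"], r2["ci_low"])
    # row order changes the resampling realization but not the inference
    perm = rng.permutation(25)
    r3 = bootstrap_paths(P[perm], n_boot=4000, seed=9)
    np.testing.assert_allclose(r1["estimate"], r3["estimate"], atol=1e-12)
    np.testing.assert_allclose(r1["p"], r3["p"], atol=0.05)
    np.testing.assert_allclose(r1["se"], r3["se"], rtol=0.1)


def test_bootstrap_guards():
    with pytest.raises(ValueError, match="5 subjects"):
        bootstrap_paths(np.ones((3, 2)), n_boot=2000)
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_paths(np.ones((10, 2)), n_boot=100)


# ---------------------------------------------------------------------------
# multilevel wrappers
# ---------------------------------------------------------------------------

def _chain_data(rng, n_subj=12, n_trials=80, a=0.5, b=0.3, noise=1.0):
    rows = []
    for s in range(n_subj):
        x = rng.normal(size=n_trials)
        m = a * x + noise * rng.normal(size=n_trials)
        y = b * m + 0.2 * x + noise * rng.normal(size=n_trials)
        rows.append(pd.DataFrame({"subject": s, "x": x, "m": m, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_multilevel_mediation_recovers_indirect_effect(rng):
    data = _chain_data(rng, n_subj=30, n_trials=95)
    res = multilevel_mediation(data, "x", "m", "y", n_boot=2000, seed=3)
    s = res.paths["ab"]
    assert abs(s.estimate - 0.15) < 2 * s.se
    assert res.significant


def test_multilevel_mediation_variance_agreement(rng):
    """Delta variances track the subject-level spread of ab estimates."""
    data = _chain_data(rng, n_subj=20, n_trials=1000)
    res = multilevel_mediation(data, "x", "m", "y", n_boot=2000, seed=4)
    est = res.subject_estimates
    mean_delta = np.mean([e.var_ab for e in est])
    # with many trials between-subject truth is constant, so the spread of
    # ab estimates is within-subject sampling noise: the delta variances
    # should agree with it within 50% at this replication level
    spread = np.var([e.ab for e in est], ddof=1)
    assert mean_delta == pytest.approx(spread, rel=0.5)


def test_three_path_reversed_chain_not_significant(rng):
    """Fitting the mediators in reversed order must kill the chain."""
    rows = []
    for s in range(20):
        n = 95
        x = rng.normal(size=n)
        m1 = 0.8 * x + 0.5 * rng.normal(size=n)
        m2 = 0.8 * m1 + 0.5 * rng.normal(size=n)
        y = 0.8 * m2 + 0.1 * x + rng.normal(size=n)
        rows.append(pd.DataFrame({"subject": s, "x": x, "m1": m1, "m2": m2, "y": y}))
    data = pd.concat(rows, ignore_index=True)
    fwd = multilevel_three_path(data, "x", "m1", "m2", "y", n_boot=2000, seed=5)
    rev = multilevel_three_path(data, "x", "m2", "m1", "y", n_boot=2000, seed=5)
    assert fwd.significant and fwd.joint_significant
    assert not rev.significant


def test_conjunction_never_looser_than_either_criterion(rng):
    """Three-path significance implies both the joint and product criteria."""
    for r in range(40):
        data = _chain_data(rng, n_subj=8, n_trials=30, a=0.2, b=0.15)
        data["m2"] = 0.3 * data["m"] + rng.normal(size=len(data))
        res = multilevel_three_path(
            data, "x", "m", "m2", "y", n_boot=1000, seed=100 + r
        )
        product_sig = res.paths["product"].p < res.alpha
        assert res.significant == (product_sig and res.joint_significant)
        assert res.significant <= product_sig
        assert res.significant <= res.joint_significant


def test_power_ordering(rng):
    """Larger path coefficients yield at least as many rejections."""
    strong = weak = 0
    for r in range(25):
        d_strong = _chain_data(rng, n_subj=30, n_trials=95, a=0.5, b=0.3)
        d_weak = _chain_data(rng, n_subj=30, n_trials=95, a=0.25, b=0.15)
        strong += multilevel_mediation(
            d_strong, "x", "m", "y", n_boot=1000, seed=200 + r
        ).significant
        weak += multilevel_mediation(
            d_weak, "x", "m", "y", n_boot=1000, seed=300 + r
        ).significant
    assert strong >= weak


def test_too_few_subjects_raises(rng):
    data = _chain_data(rng, n_subj=4)
    with pytest.raises(ValueError, match="5"):
        multilevel_mediation(data, "x", "m", "y", n_boot=1000, seed=1)


# ---------------------------------------------------------------------------
# voxel-wise search
# ---------------------------------------------------------------------------

def test_single_voxel_search_equals_scalar_pipeline(rng):
    data = _chain_data(rng, n_subj=10, n_trials=60)
    scalar = multilevel_mediation(data, "x", "m", "y", n_boot=2000, seed=77)
    subject_data = [
        {
            "x": d["x"].to_numpy(),
            "y": d["y"].to_numpy(),
            "betas": d["m"].to_numpy()[:, None],
        }
        for _, d in data.groupby("subject")
    ]
    res = mediation_brain_search(subject_data, mode="two_path", n_boot=2000, seed=77)
    for j, name in enumerate(res["names"]):
        assert res[name][0] == pytest.approx(
            scalar.paths[name].estimate, abs=1e-10
        )
    assert res["p_ab"][0] == pytest.approx(scalar.paths["ab"].p, abs=1e-9)


def test_search_skips_dead_voxels(rng):
    data = _chain_data(rng, n_subj=8, n_trials=40)
    subject_data = []
    for _, d in data.groupby("subject"):
        betas = np.column_stack([d["m"].to_numpy(), np.zeros(len(d))])
        subject_data.append(
            {"x": d["x"].to_numpy(), "y": d["y"].to_numpy(), "betas": betas}
        )
    res = mediation_brain_search(subject_data, mode="two_path", n_boot=1000, seed=8)
    assert not res["skipped"][0]
    assert res["skipped"][1]
    assert np.isnan(res["ab"][1])
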
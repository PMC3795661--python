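"""RDA engine: transform, fits, adjusted R2, permutation inference, selection."""

import numpy as np
import pytest

from scalescape import (
    ValidationError,
    adjusted_r2,
    aem_basis,
    fit_rda,
    forward_select,
    hellinger_transform,
    permutation_pvalue,
)
from scalescape import test_axes as sequential_axis_tests


# -- Hellinger ---------------------------------------------------------------

def test_hellinger_hand_examples_and_unit_rows():
    y = np.array([[4.0, 0.0, 0.0], [1.0, 1.0, 2.0]])
    h = hellinger_transform(y)
    np.testing.assert_allclose(h[0], [1.0, 0.0, 0.0])
    np.testing.assert_allclose(h[1], [0.5, 0.5, 0.70710678], atol=1e-8)
    rng = np.random.default_rng(0)
    h2 = hellinger_transform(rng.lognormal(size=(10, 6)))
    np.testing.assert_allclose((h2**2).sum(axis=1), 1.0, atol=1e-12)


def test_hellinger_rejects_zero_rows():
    with pytest.raises(ValidationError, match="zero-sum"):
        hellinger_transform(np.array([[1.0, 1.0], [0.0, 0.0]]))


# -- fit_rda ------------------------------------------------------------------

def test_exact_fit_gives_r2_one_and_lc_collinear_with_predictor():
    n = 12
    x = np.linspace(-1, 1, n)[:, None]
    y = np.column_stack([2.0 + 3.0 * x[:, 0]])
    model = fit_rda(y, x)
    assert model.r2 == pytest.approx(1.0)
    assert model.lc_scores.shape[1] == 1
    r = np.corrcoef(model.lc_scores[:, 0], x[:, 0])[0, 1]
    assert abs(r) == pytest.approx(1.0)


def test_r2_matches_per_column_regression_oracle():
    """With orthonormal centered X, model R2 equals the sum over predictors of
    squared simple-regression contributions, computed column by column here."""
    rng = np.random.default_rng(3)
    n, m, p = 20, 4, 6
    x = np.linalg.qr(rng.normal(size=(n, m)) - 0.5)[0]
    x = x - x.mean(axis=0)
    x, _ = np.linalg.qr(x)
    y = rng.normal(size=(n, p))
    yc = y - y.mean(axis=0)
    ss_fit_oracle = 0.0
    for j in range(m):
        xj = x[:, j]
        for k in range(p):
            beta = (xj @ yc[:, k]) / (xj @ xj)
            ss_fit_oracle += beta**2 * (xj @ xj)
    model = fit_rda(y, x)
    assert model.r2 == pytest.approx(ss_fit_oracle / np.sum(yc**2), rel=1e-10)


def test_taxon_permutation_equivariance_and_eigenvalue_conservation():
    rng = np.random.default_rng(4)
    y = rng.normal(size=(15, 8))
    x = rng.normal(size=(15, 3))
    model = fit_rda(y, x)
    yc = y - y.mean(axis=0)
    total_var = np.sum(yc**2) / (15 - 1)
    assert model.canonical_eigenvalues.sum() == pytest.approx(
        model.r2 * total_var, rel=1e-10
    )
    perm = rng.permutation(8)
    model_p = fit_rda(y[:, perm], x)
    np.testing.assert_allclose(
        model_p.species_scores, model.species_scores[perm], atol=1e-8
    )
    np.testing.assert_allclose(model_p.lc_scores, model.lc_scores, atol=1e-8)
    assert model_p.r2 == pytest.approx(model.r2)


def test_lc_scores_lie_in_predictor_column_space():
    rng = np.random.default_rng(5)
    y = rng.normal(size=(18, 10))
    x = rng.normal(size=(18, 4))
    model = fit_rda(y, x)
    xc = x - x.mean(axis=0)
    q, _ = np.linalg.qr(xc)
    resid = model.lc_scores - q @ (q.T @ model.lc_scores)
    assert np.abs(resid).max() < 1e-10


def test_collinear_predictors_error_names_columns():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(10, 2))
    x = np.column_stack([x, x[:, 0] + x[:, 1]])
    with pytest.raises(ValidationError, match=r"collinear.*\[2\]"):
        fit_rda(rng.normal(size=(10, 4)), x)


# -- adjusted R2 --------------------------------------------------------------

def test_adjusted_r2_values_and_bounds():
    assert adjusted_r2(1.0, 24, 5) == pytest.approx(1.0)
    assert adjusted_r2(0.0, 24, 5) == pytest.approx(1.0 - 23.0 / 18.0)
    for r2 in (0.1, 0.5, 0.9):
        assert adjusted_r2(r2, 24, 3) <= r2
    with pytest.raises(ValidationError):
        adjusted_r2(0.5, 6, 5)


# -- permutation test ---------------------------------------------------------

def test_saturated_response_attains_minimum_p():
    x = aem_basis(12).retained_eigenfunctions()[:, :2]
    y = x @ np.array([[1.0, 0.5], [0.2, -1.0]])
    p = permutation_pvalue(y, x, n_perm=199, seed=0)
    assert p == pytest.approx(1.0 / 200.0)


def test_p_invariant_to_predictor_order_and_seed_reproducible():
    rng = np.random.default_rng(7)
    y = rng.normal(size=(16, 5))
    x = rng.normal(size=(16, 3))
    p1 = permutation_pvalue(y, x, n_perm=199, seed=11)
    p2 = permutation_pvalue(y, x[:, ::-1], n_perm=199, seed=11)
    p3 = permutation_pvalue(y, x, n_perm=199, seed=11)
    assert p1 == p2 == p3


def test_p_converges_for_large_permutation_counts():
    rng = np.random.default_rng(8)
    x = aem_basis(24).retained_eigenfunctions()[:, :3]
    y = x @ rng.normal(size=(3, 6)) * 0.4 + rng.normal(size=(24, 6))
    p1 = permutation_pvalue(y, x, n_perm=9999, seed=1)
    p2 = permutation_pvalue(y, x, n_perm=9999, seed=2)
    assert abs(p1 - p2) < 0.01


# -- forward selection --------------------------------------------------------

def test_single_matching_candidate_is_selected():
    basis = aem_basis(16)
    x = basis.retained_eigenfunctions()
    y = np.column_stack([x[:, 2], x[:, 2] * 0.5])
    sel = forward_select(y, x[:, [2]], n_perm=199, seed=0)
    assert sel == [0]


def test_planted_candidates_recovered():
    """Response built from candidates {1, 4} plus small noise: the pair is
    recovered in at least 90% of 50 seeds."""
    basis = aem_basis(24)
    x = basis.retained_eigenfunctions()
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        signal = x[:, [1, 4]] @ rng.normal(size=(2, 8))
        y = signal + rng.normal(scale=0.08, size=(24, 8))
        sel = forward_select(y, basis, alpha=0.05, n_perm=999, seed=seed)
        hits += set(sel) == {1, 4}
    assert hits >= 45


def test_pure_noise_yields_empty_selection():
    """The global-test gate keeps the false-selection rate near alpha."""
    basis = aem_basis(24)
    empty = 0
    for seed in range(100):
        rng = np.random.default_rng(10_000 + seed)
        y = rng.normal(size=(24, 10))
        sel = forward_select(y, basis, alpha=0.05, n_perm=99, seed=seed)
        empty += not sel
    assert empty >= 88     # binomial 99% band around 95/100


# -- axis tests ---------------------------------------------------------------

def test_exact_one_axis_model_minimum_p():
    x = aem_basis(12).retained_eigenfunctions()[:, :1]
    y = np.column_stack([x[:, 0] * 2.0, x[:, 0] * -1.0])
    model = fit_rda(y, x)
    p = sequential_axis_tests(model, y, x, n_perm=199, seed=0)
    assert p[0] == pytest.approx(1.0 / 200.0)
    assert model.n_significant_axes == 1


def test_two_planted_scales_detected():
    """Two well-separated response groups -> exactly 2 significant axes in
    at least 80% of 50 seeds."""
    basis = aem_basis(24)
    x_all = basis.retained_eigenfunctions()
    ok = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        g1 = np.outer(x_all[:, 1], rng.normal(1.0, 0.1, size=6))
        g2 = np.outer(x_all[:, 5], rng.normal(1.0, 0.1, size=4))
        y = np.column_stack([g1, g2]) + rng.normal(scale=0.25, size=(24, 10))
        sel = forward_select(y, basis, n_perm=199, seed=seed)
        if not sel:
            continue
        x = x_all[:, sel]
        model = fit_rda(y, x, selected=sel)
        sequential_axis_tests(model, y, x, n_perm=199, seed=seed + 1)
        ok += model.n_significant_axes == 2
    assert ok >= 40


def test_joint_time_relabelling_preserves_observed_statistics():
    """Shuffling the rows of response and predictors identically leaves the
    fit and the observed permutation statistics unchanged; p-values agree
    in distribution (checked on Monte Carlo means)."""
    rng = np.random.default_rng(9)
    x_all = aem_basis(18).retained_eigenfunctions()
    x = x_all[:, :3]
    y = x @ rng.normal(size=(3, 5)) * 0.5 + rng.normal(size=(18, 5))
    perm = rng.permutation(18)
    m1 = fit_rda(y, x)
    m2 = fit_rda(y[perm], x[perm])
    np.testing.assert_allclose(
        m2.canonical_eigenvalues, m1.canonical_eigenvalues, atol=1e-10
    )
    assert m2.r2 == pytest.approx(m1.r2, rel=1e-12)
    p_orig = np.mean(
        [permutation_pvalue(y, x, n_perm=99, seed=s) for s in range(30)]
    )
    p_shuf = np.mean(
        [permutation_pvalue(y[perm], x[perm], n_perm=99, seed=s) for s in range(30)]
    )
    assert abs(p_orig - p_shuf) < 0.1
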
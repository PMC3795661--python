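"""Diversity metrics identities and the repeated-measures ANOVA oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalescape import CommunityTimeSeries, ValidationError, compute_metrics, fit_rm_anova
from scalescape.metrics import _orthonormal_contrasts


def _cts_from_rows(rows) -> CommunityTimeSeries:
    rows = np.asarray(rows, dtype=float)
    return CommunityTimeSeries(
        site_id="s", state_id="w",
        times=np.arange(1, len(rows) + 1),
        taxa=[f"t{i}" for i in range(rows.shape[1])],
        biovolume=rows,
    )


@pytest.mark.parametrize(
    "row, s, h, d, e",
    [
        ([5.0, 0.0, 0.0], 1, 0.0, 1.0, 1.0),                 # single taxon
        ([2.0, 2.0, 2.0, 2.0], 4, np.log(4), 4.0, 1.0),      # equal shares
        ([1.0, 1.0, 2.0], 3, 1.0397208, 2.8284271, 0.9428090),
    ],
)
def test_metric_identities(row, s, h, d, e):
    """Shannon in nats, diversity = exp(H), evenness = D/S, hand-checked."""
    m = compute_metrics(_cts_from_rows([row, row, row])).iloc[0]
    assert m.richness == s
    assert m.shannon == pytest.approx(h, abs=1e-6)
    assert m.diversity == pytest.approx(d, abs=1e-6)
    assert m.evenness == pytest.approx(e, abs=1e-6)
    assert m.total_biovolume == pytest.approx(sum(row))


def test_all_zero_step_is_flagged_undefined():
    m = compute_metrics(_cts_from_rows([[1, 1], [0, 0], [2, 1]]))
    assert not m.loc[1, "defined"]
    assert np.isnan(m.loc[1, "shannon"])
    assert m.loc[[0, 2], "defined"].all()


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_hill_identities_and_taxon_order_invariance(seed):
    """D = exp(H) and E = D/S to machine precision; metrics ignore taxon order."""
    rng = np.random.default_rng(seed)
    bio = rng.lognormal(size=(5, 7)) * (rng.random((5, 7)) > 0.2)
    bio[bio.sum(axis=1) == 0, 0] = 1.0
    m = compute_metrics(_cts_from_rows(bio))
    assert np.allclose(m.diversity, np.exp(m.shannon))
    assert np.allclose(m.evenness, m.diversity / m.richness)
    assert ((m.diversity >= 1 - 1e-12) & (m.diversity <= m.richness + 1e-9)).all()
    perm = rng.permutation(7)
    m2 = compute_metrics(_cts_from_rows(bio[:, perm]))
    for col in ("richness", "shannon", "diversity", "evenness", "total_biovolume"):
        np.testing.assert_allclose(m[col], m2[col])


# ---------------------------------------------------------------------------
# rm-ANOVA: brute-force summation oracle, written independently of the module
# ---------------------------------------------------------------------------

def brute_force_rm_anova(y: np.ndarray) -> dict:
    """Explicit cell-means decomposition by direct summation (oracle)."""
    n, a, b = y.shape
    grand = sum(y[s, i, j] for s in range(n) for i in range(a) for j in range(b))
    grand /= n * a * b
    out = {}
    ss_a = ss_b = ss_ab = ss_as = ss_bs = 0.0
    for i in range(a):
        m = np.mean([y[s, i, j] for s in range(n) for j in range(b)])
        ss_a += n * b * (m - grand) ** 2
    for j in range(b):
        m = np.mean([y[s, i, j] for s in range(n) for i in range(a)])
        ss_b += n * a * (m - grand) ** 2
    for i in range(a):
        for j in range(b):
            m_ab = np.mean([y[s, i, j] for s in range(n)])
            m_a = np.mean([y[s, i, jj] for s in range(n) for jj in range(b)])
            m_b = np.mean([y[s, ii, j] for s in range(n) for ii in range(a)])
            ss_ab += n * (m_ab - m_a - m_b + grand) ** 2
    for s in range(n):
        m_s = np.mean([y[s, i, j] for i in range(a) for j in range(b)])
        for i in range(a):
            m_sa = np.mean([y[s, i, j] for j in range(b)])
            m_a = np.mean([y[ss, i, j] for ss in range(n) for j in range(b)])
            ss_as += b * (m_sa - m_s - m_a + grand) ** 2
        for j in range(b):
            m_sb = np.mean([y[s, i, j] for i in range(a)])
            m_b = np.mean([y[ss, i, j] for ss in range(n) for i in range(a)])
            ss_bs += a * (m_sb - m_s - m_b + grand) ** 2
    ss_tot = sum(
        (y[s, i, j] - grand) ** 2
        for s in range(n) for i in range(a) for j in range(b)
    )
    ss_subj = sum(
        a * b * (np.mean(y[s]) - grand) ** 2 for s in range(n)
    )
    ss_abs = ss_tot - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    out["State"] = (ss_a, a - 1, ss_as, (a - 1) * (n - 1))
    out["Time"] = (ss_b, b - 1, ss_bs, (b - 1) * (n - 1))
    out["State:Time"] = (ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1))
    out["ss_total"] = ss_tot
    return out


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_anova_matches_brute_force_oracle(seed):
    """SS, uncorrected df, MS and F agree with explicit summation on 3x2x4 data."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=(3, 2, 4))
    res = fit_rm_anova(y).table
    oracle = brute_force_rm_anova(y)
    for effect in ("State", "Time", "State:Time"):
        ss_eff, df_eff, ss_err, df_err = oracle[effect]
        row = res.loc[effect]
        assert row.ss == pytest.approx(ss_eff, rel=1e-10)
        # corrected df = uncorrected df * epsilon
        assert row.df_num == pytest.approx(df_eff * row.epsilon_hf, rel=1e-12)
        assert row.df_den == pytest.approx(df_err * row.epsilon_hf, rel=1e-12)
        assert row.ms == pytest.approx(ss_eff / df_eff, rel=1e-10)
        assert row.F == pytest.approx(
            (ss_eff / df_eff) / (ss_err / df_err), rel=1e-10
        )
        assert 1.0 / df_eff <= row.epsilon_hf <= 1.0 or df_eff == 1
    assert res.attrs["ss_total"] == pytest.approx(oracle["ss_total"], rel=1e-10)


def test_spherical_covariance_gives_epsilon_one():
    """Exactly spherical contrast covariance -> Huynh-Feldt epsilon = 1."""
    n, b = 5, 4
    c = _orthonormal_contrasts(b)                 # (b-1, b)
    basis = np.linalg.qr(
        np.column_stack([np.ones(n), np.eye(n)[:, : b - 1]])
    )[0][:, 1:]                                   # (n, b-1) orthonormal, zero-mean
    profile = basis @ c                           # spherical by construction
    y = np.stack([profile + 1.0, profile + 3.0], axis=1)   # identical across states
    res = fit_rm_anova(y).table
    assert np.allclose(res.epsilon_hf, 1.0)
    assert res.loc["Time", "df_num"] == pytest.approx(b - 1)
    assert res.loc["Time", "df_den"] == pytest.approx((b - 1) * (n - 1))


def test_constant_input_flags_undefined_f():
    y = np.full((3, 2, 4), 2.5)
    res = fit_rm_anova(y).table
    assert np.allclose(res.ms, 0.0)
    assert res.F.isna().all()


def test_epsilon_correction_never_lowers_p():
    """For the same F, epsilon-shrunken df give a p at least as large."""
    rng = np.random.default_rng(5)
    # strong time effect plus non-sphericity (one time dominates the covariance)
    y = rng.normal(size=(6, 2, 5))
    y += np.arange(5) * 1.5                                 # big Time effect
    y[:, :, 0] += rng.normal(scale=6.0, size=(6, 1)) * np.ones((6, 2))
    res = fit_rm_anova(y).table
    from scipy import stats

    checked = 0
    for effect in ("Time", "State:Time"):
        row = res.loc[effect]
        eps = row.epsilon_hf
        assert eps <= 1.0
        if row.F < 1.0:
            continue  # df shrinkage is conservative only above F = 1
        p_uncorr = stats.f.sf(row.F, row.df_num / eps, row.df_den / eps)
        assert row.p >= p_uncorr - 1e-12
        checked += 1
    assert checked >= 1


def test_incomplete_design_is_rejected():
    y = np.random.default_rng(0).normal(size=(3, 2, 4))
    y[1, 0, 2] = np.nan
    with pytest.raises(ValidationError, match="incomplete"):
        fit_rm_anova(y)
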
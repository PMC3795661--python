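"""Redundancy analysis on temporal eigenfunctions with permutation inference.

The time-series model is a constrained ordination: the Hellinger-transformed
community matrix is regressed on a forward-selected subset of AEM
eigenfunctions, and the eigen-decomposition of the fitted values yields
canonical axes, each one modelled fluctuation pattern shared by a group of
taxa.  Inference is by unrestricted row permutation throughout: a global
pseudo-F test gates the forward selection, each added predictor is tested by
reduced-model residual permutation, and canonical axes are tested
sequentially (axis k conditioned on axes 1..k-1), stopping at the first
non-significant axis.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AEMBasis, RDAModel, ValidationError

_RANK_RTOL = 1e-9


def hellinger_transform(y: np.ndarray) -> np.ndarray:
    """Square root of row proportions: cell (i,j) -> sqrt(y_ij / rowsum_i).

    Gives abundance data a Euclidean geometry suitable for RDA; every output
    row has unit sum of squares.  Rows summing to zero are undefined and
    rejected.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValidationError("negative values in community matrix")
    rowsums = y.sum(axis=1)
    if np.any(rowsums <= 0):
        bad = np.nonzero(rowsums <= 0)[0]
        raise ValidationError(f"zero-sum rows at positions {bad.tolist()}")
    return np.sqrt(y / rowsums[:, None])


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel-adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n <= m + 1:
        raise ValidationError(f"need n > m + 1, got n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _centered(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x - x.mean(axis=0)


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of a centered predictor matrix."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > max(diag.max(), 1.0) * _RANK_RTOL if len(diag) else diag > 0
    if not keep.all():
        bad = np.nonzero(~keep)[0].tolist()
        raise ValidationError(f"collinear predictor columns at positions {bad}")
    return q


def fit_rda(y_t: np.ndarray, x: np.ndarray, selected: list[int] | None = None) -> RDAModel:
    """Fit a redundancy analysis of a (transformed) response on predictors.

    ``y_t`` is column-centered internally; fitted values come from least
    squares on the centered predictors, and the SVD of the fitted matrix
    gives canonical axes.  Canonical eigenvalues are on the variance scale
    (divided by n - 1) so that they sum to r2 times the total variance of
    the centered response.
    """
    yc = _centered(y_t)
    xc = _centered(x)
    n, p = yc.shape
    m = xc.shape[1]
    if n <= m + 1:
        raise ValidationError(f"need n_time > n_predictors + 1 ({n} vs {m})")
    q = _orth_basis(xc)
    proj = q.T @ yc
    fitted = q @ proj
    ss_tot = float(np.sum(yc**2))
    ss_fit = float(np.sum(proj**2))
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > (s[0] if len(s) else 0.0) * _RANK_RTOL
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # reproducible axis orientation: first nonzero lc-score element positive
    for k in range(u.shape[1]):
        nz = np.nonzero(np.abs(u[:, k]) > 1e-12)[0]
        if len(nz) and u[nz[0], k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]
    eigenvalues = s**2 / (n - 1)
    lc_scores = u * s
    species_scores = vt.T
    coeffs, *_ = np.linalg.lstsq(xc, fitted, rcond=None)
    adj = adjusted_r2(r2, n, m)
    share = eigenvalues / eigenvalues.sum() if eigenvalues.sum() > 0 else eigenvalues
    return RDAModel(
        selected=list(selected) if selected is not None else list(range(m)),
        coefficients=coeffs,
        canonical_eigenvalues=eigenvalues,
        lc_scores=lc_scores,
        species_scores=species_scores,
        r2=r2,
        adj_r2=adj,
        axis_adj_r2=share * adj,
    )


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def permutation_pvalue(
    y_t: np.ndarray, x: np.ndarray, n_perm: int = 999, seed: int = 0
) -> float:
    """Global permutation test of the full model.

    pseudo-F = (SS_fit / m) / (SS_resid / (n - m - 1)) compared against its
    distribution under unrestricted row permutation of the response;
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    yc = _centered(y_t)
    q = _orth_basis(_centered(x))
    n, m = yc.shape[0], q.shape[1]
    ss_tot = float(np.sum(yc**2))
    f_obs = _pseudo_f(float(np.sum((q.T @ yc) ** 2)), ss_tot, n, m)

    rng = np.random.default_rng(seed)
    idx = _perm_indices(rng, n, n_perm)
    yp = yc[idx]                        # (n_perm, n, p); stays column-centered
    ss_fit_p = np.einsum("kn,bnp->bkp", q.T, yp)
    ss_fit_p = np.sum(ss_fit_p**2, axis=(1, 2))
    f_perm = _pseudo_f(ss_fit_p, ss_tot, n, m)
    return float((np.sum(f_perm >= f_obs) + 1) / (n_perm + 1))


def _pseudo_f(ss_fit, ss_tot, n, m):
    ss_fit = np.asarray(ss_fit, dtype=float)
    resid = np.maximum(ss_tot - ss_fit, 0.0)   # clamp rounding of saturated fits
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.divide(ss_fit / m, resid / (n - m - 1))


def forward_select(
    y_t: np.ndarray,
    candidates: AEMBasis | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> list[int]:
    """Forward selection of temporal predictors with the double stopping rule.

    The global model (all candidates) is tested first: if its permutation p
    exceeds ``alpha`` the selection is empty — the community carries no
    detectable temporal structure at this level.  Otherwise predictors are
    added greedily (largest fit gain).  The best candidate's permutation p
    is computed against a max-statistic null (the largest gain among all
    remaining candidates under row permutation of the current residuals), so
    picking the best of many candidates does not inflate the per-step error
    rate.  Selection stops when that p exceeds ``alpha``; when the cumulative
    adjusted R^2 passes the global model's, the variable that crossed is kept
    and selection stops (double stopping).  Returned indices are column
    positions into the candidate matrix, in selection order.
    """
    if isinstance(candidates, AEMBasis):
        x_all = candidates.retained_eigenfunctions()
    else:
        x_all = np.asarray(candidates, dtype=float)
    yc = _centered(y_t)
    n, n_cand = yc.shape[0], x_all.shape[1]
    if n_cand < 1:
        raise ValidationError("need at least one candidate predictor")
    rng = np.random.default_rng(seed)

    p_global = permutation_pvalue(
        yc, x_all, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
    )
    if p_global > alpha:
        return []
    q_all = _orth_basis(_centered(x_all))
    ss_tot = float(np.sum(yc**2))
    adj_r2_global = adjusted_r2(
        float(np.sum((q_all.T @ yc) ** 2)) / ss_tot, n, q_all.shape[1]
    )

    selected: list[int] = []
    q_sel = np.empty((n, 0))
    resid = yc.copy()
    while len(selected) < n_cand:
        # fit gain of each remaining candidate, orthogonalized on selection
        remaining, qcs, gains = [], [], []
        for j in range(n_cand):
            if j in selected:
                continue
            v = _centered(x_all[:, j])[:, 0]
            v = v - q_sel @ (q_sel.T @ v)
            norm = np.linalg.norm(v)
            if norm < 1e-10:
                continue
            remaining.append(j)
            qcs.append(v / norm)
            gains.append(float(np.sum((qcs[-1] @ resid) ** 2)))
        if not remaining:
            break
        best = int(np.argmax(gains))
        best_j, best_gain, best_qc = remaining[best], gains[best], qcs[best]
        m_sel = len(selected)
        if n - m_sel - 2 < 1:
            break
        # max-statistic reduced-model permutation test of the best candidate
        q_rem = np.column_stack(qcs)                  # (n, n_remaining)
        idx = _perm_indices(rng, n, n_perm)
        rp = resid[idx]
        gain_p = np.sum(np.einsum("nc,bnp->bcp", q_rem, rp) ** 2, axis=2)
        max_gain_p = gain_p.max(axis=1)
        p_val = float((np.sum(max_gain_p >= best_gain) + 1) / (n_perm + 1))
        if p_val > alpha:
            break
        selected.append(best_j)
        q_sel = np.column_stack([q_sel, best_qc])
        resid = resid - np.outer(best_qc, best_qc @ resid)
        # double stopping: once the cumulative adjusted R^2 passes the global
        # model's, the variable that crossed is kept and selection stops
        ss_fit_new = float(np.sum((q_sel.T @ yc) ** 2))
        if adjusted_r2(ss_fit_new / ss_tot, n, m_sel + 1) > adj_r2_global:
            break
    return selected


def _partial_f(gain, ss_resid, df_den):
    gain = np.asarray(gain, dtype=float)
    resid = np.maximum(ss_resid - gain, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.divide(gain, resid / df_den)


def test_axes(
    model: RDAModel,
    y_t: np.ndarray,
    x: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Sequential permutation tests of the canonical axes.

    Axis k is tested conditioning on the fitted structure of axes 1..k-1:
    their lc-score space is partialled out of both response and predictors,
    the rows of the residual response are permuted, and the first canonical
    eigenvalue of the partial fit forms the null distribution.  Testing
    stops at the first non-significant axis; untested axes report NaN.  The
    count of leading significant axes is the model's temporal scale count.
    """
    yc = _centered(y_t)
    xc = _centered(x)
    n, m = yc.shape[0], xc.shape[1]
    q_x = _orth_basis(xc)
    fitted = q_x @ (q_x.T @ yc)
    ss_resid_full = float(np.sum((yc - fitted) ** 2))
    df_den = n - m - 1
    rng = np.random.default_rng(seed)

    n_axes = model.lc_scores.shape[1]
    pvals = np.full(n_axes, np.nan)
    u = model.lc_scores / np.linalg.norm(model.lc_scores, axis=0)
    for k in range(n_axes):
        z = u[:, :k]                          # conditioning axes
        y_r = yc - z @ (z.T @ yc)
        q_r = _orth_basis_partial(q_x, z)
        lam_obs = float(_first_axis_stat(q_r.T @ y_r))
        f_obs = lam_obs / (ss_resid_full / df_den) if ss_resid_full > 0 else np.inf
        idx = _perm_indices(rng, n, n_perm)
        yp = y_r[idx]
        if k:
            yp = yp - np.einsum("nk,bkp->bnp", z, np.einsum("kn,bnp->bkp", z.T, yp))
        proj = np.einsum("kn,bnp->bkp", q_r.T, yp)
        # first canonical eigenvalue of each permuted partial fit
        lam_p = _first_axis_stat(proj)
        resid_p = np.sum(yp**2, axis=(1, 2)) - np.sum(proj**2, axis=(1, 2))
        f_perm = lam_p / (resid_p / df_den)
        if ss_resid_full <= 0:
            p = 1.0 / (n_perm + 1)
        else:
            p = float((np.sum(f_perm >= f_obs) + 1) / (n_perm + 1))
        pvals[k] = p
        if p > alpha:
            break
    model.axis_pvalues = pvals
    model._alpha_used = alpha
    model.n_perm = n_perm
    model.seed = seed
    return pvals


def _orth_basis_partial(q_x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(q_x) orthogonal to span(z)."""
    if z.shape[1] == 0:
        return q_x
    r = q_x - z @ (z.T @ q_x)
    q, rr = np.linalg.qr(r)
    diag = np.abs(np.diag(rr))
    keep = diag > max(diag.max(), 1.0) * 1e-8
    return q[:, keep]


def _first_axis_stat(proj: np.ndarray) -> np.ndarray:
    return np.linalg.svd(proj, compute_uv=False)[..., 0] ** 2
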
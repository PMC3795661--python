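"""Asymmetric-eigenvector-map (AEM) temporal variables.

Time flows one way, so the connectivity of a regular time series is the
directed chain 1 -> 2 -> ... -> n.  Each time step is described by the set of
links through which it is reached, giving a binary sites-by-edges incidence
matrix whose centered singular vectors are orthogonal temporal eigenfunctions:
the first models a linear trend and the rest capture fluctuations from slow to
increasingly fast.  Only eigenfunctions modelling *positive* temporal
autocorrelation — Moran's I above its null expectation -1/(n-1) under
consecutive-step contiguity — are retained as candidate predictors; for
n = 24 monthly steps this yields 12 variables.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import AEMBasis, ValidationError

logger = logging.getLogger(__name__)

_SV_RTOL = 1e-10  # relative singular-value cutoff for rank decisions


def build_time_incidence(n_time: int) -> np.ndarray:
    """Binary incidence of the directed linear time graph.

    Row i (0-based) carries 1 in columns 0..i-1: time step i+1 is reached
    through all i earlier links.  The first row is all zeros and row sums
    are 0, 1, ..., n-1.
    """
    if n_time < 3:
        raise ValidationError(f"need n_time >= 3, got {n_time}")
    return np.tril(np.ones((n_time, n_time - 1)), k=-1)


def _morans_i_successive(u: np.ndarray) -> float:
    """Moran's I with binary weights linking consecutive time steps."""
    z = u - u.mean()
    n = len(z)
    num = 2.0 * np.sum(z[:-1] * z[1:])   # symmetric weight sum over both directions
    s0 = 2.0 * (n - 1)
    return float(n / s0 * num / np.sum(z * z))


def compute_aem(incidence: np.ndarray) -> AEMBasis:
    """Extract temporal eigenfunctions from an incidence matrix.

    Columns are centered and decomposed by SVD; left singular vectors with
    non-negligible singular value become unit-norm eigenfunctions with
    eigenvalues equal to squared singular values (descending).  Moran's I is
    computed per eigenfunction and the retention flag marks those above the
    null expectation -1/(n-1), i.e. positive temporal autocorrelation.
    Within the retained set the ordering is slow to fast.
    """
    e = np.asarray(incidence, dtype=float)
    n = e.shape[0]
    centered = e - e.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > s[0] * _SV_RTOL
    if keep.sum() < len(s):
        logger.info("dropping %d near-null singular values", len(s) - keep.sum())
    u, s = u[:, keep], s[keep]
    morans = np.array([_morans_i_successive(u[:, j]) for j in range(u.shape[1])])
    retained = morans > (-1.0 / (n - 1))
    basis = AEMBasis(
        n_time=n,
        incidence=e,
        eigenfunctions=u,
        eigenvalues=s**2,
        morans_i=morans,
        retained=retained,
    )
    return sign_fix(basis)


def sign_fix(basis: AEMBasis) -> AEMBasis:
    """Make each eigenfunction's first nonzero element positive (idempotent).

    SVD signs are arbitrary; fixing them makes output reproducible across
    platforms.  Moran's I and eigenvalues are sign-invariant and untouched.
    """
    u = basis.eigenfunctions.copy()
    for j in range(u.shape[1]):
        col = u[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            u[:, j] = -col
    basis.eigenfunctions = u
    return basis


def aem_basis(n_time: int) -> AEMBasis:
    """Convenience: incidence + decomposition + sign fix in one call."""
    return compute_aem(build_time_incidence(n_time))
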
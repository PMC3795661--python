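"""Community metrics and repeated-measures ANOVA.

Metrics per time step: richness S (taxa with positive biovolume), Shannon
entropy H (nats, on biovolume proportions), diversity D = exp(H) (the Hill
number of order 1, an effective number of equally abundant taxa), evenness
E = D / S (mathematically independent of richness), and total biovolume.

The ANOVA is a two-factor within-subjects (State x Time) repeated-measures
decomposition with sites as subjects, Type III sums of squares (identical to
the sequential sums in the balanced designs this module accepts), and
Huynh-Feldt correction of the degrees of freedom of within-subject effects
whose sphericity is in doubt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CommunityTimeSeries, ValidationError


def compute_metrics(cts: CommunityTimeSeries) -> pd.DataFrame:
    """Per-time-step community metrics as a tidy table.

    Returns a DataFrame with columns ``time, richness, shannon, diversity,
    evenness, total_biovolume, defined``.  A time step whose biovolume is
    all zero has no defined composition; it is flagged ``defined=False``
    with NaN metrics rather than silently zeroed.
    """
    rows = []
    for i, t in enumerate(cts.times):
        y = cts.biovolume[i]
        total = float(y.sum())
        if total <= 0:
            rows.append((t, 0, np.nan, np.nan, np.nan, 0.0, False))
            continue
        pos = y[y > 0]
        p = pos / total
        s = int(len(pos))
        h = float(-(p * np.log(p)).sum())
        d = float(np.exp(h))
        rows.append((t, s, h, d, d / s, total, True))
    return pd.DataFrame(
        rows,
        columns=[
            "time", "richness", "shannon", "diversity",
            "evenness", "total_biovolume", "defined",
        ],
    )


@dataclass
class RmAnovaTable:
    """Type III repeated-measures ANOVA with Huynh-Feldt corrected df.

    ``table`` has one row per effect (State, Time, State:Time) with columns
    ``ss, df_num, df_den, ms, ms_error, F, p, epsilon_hf``; df are already
    multiplied by the effect's Huynh-Feldt epsilon.  An all-constant input
    yields zero mean squares and NaN F (flagged undefined, not an error).
    """

    table: pd.DataFrame

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def _hf_epsilon(scores: np.ndarray, ref_scale: float = 1.0) -> float:
    """Huynh-Feldt epsilon from subject scores on orthonormal effect contrasts.

    ``scores`` is (n_subjects, df_effect): the data multiplied by an
    orthonormal contrast basis of the effect.  Greenhouse-Geisser epsilon is
    computed from the sample covariance of these scores, then the Huynh-Feldt
    adjustment is applied and capped at 1.  Scores that vanish relative to
    ``ref_scale`` (the data's spread) carry no sphericity information and
    yield epsilon 1.
    """
    n, k = scores.shape
    if k == 1:
        return 1.0
    if float(np.max(np.abs(scores), initial=0.0)) <= 1e-10 * max(ref_scale, 1e-300):
        return 1.0  # degenerate (no between-subject variation): sphericity moot
    m = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0:
        return 1.0
    eps_gg = tr**2 / (k * tr2)
    num = n * k * eps_gg - 2.0
    den = k * (n - 1 - k * eps_gg)
    eps_hf = eps_gg if den <= 0 else num / den
    return float(min(1.0, max(eps_hf, 1.0 / k)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts spanning the space orthogonal to 1."""
    h = np.linalg.qr(
        np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    )[0][:, 1:]
    return h.T


def fit_rm_anova(values: np.ndarray, log_transform: bool = False) -> RmAnovaTable:
    """Two-factor within-subjects ANOVA on a (subjects, states, times) array.

    Subjects (sites) must be observed in every state x time cell; an
    incomplete (NaN-containing) array is rejected — drop incomplete subjects
    before calling.  ``log_transform`` applies ln(x + 1) first (for
    right-skewed metrics such as total biovolume).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValidationError("values must be (subjects, states, times)")
    if np.any(~np.isfinite(y)):
        raise ValidationError(
            "incomplete design: drop subjects with missing cells before fitting"
        )
    if log_transform:
        y = np.log(y + 1.0)
    n, a, b = y.shape
    if n < 2:
        raise ValidationError("need at least 2 subjects")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))           # subject means
    m_a = y.mean(axis=(0, 2))           # state means
    m_b = y.mean(axis=(0, 1))           # time means
    m_sa = y.mean(axis=2)               # (n, a)
    m_sb = y.mean(axis=1)               # (n, b)
    m_ab = y.mean(axis=0)               # (a, b)

    ss_subj = a * b * ((m_s - grand) ** 2).sum()
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_abs = ss_tot - (ss_subj + ss_a + ss_b + ss_as + ss_bs + ss_ab)

    # orthonormal contrast scores per effect, for the sphericity estimate
    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    scores_a = m_sa @ c_a.T * np.sqrt(b)
    scores_b = m_sb @ c_b.T * np.sqrt(a)
    cells = y.reshape(n, a * b)
    c_ab = np.kron(c_a, c_b)
    scores_ab = cells @ c_ab.T

    ref_scale = float(np.max(np.abs(y - grand), initial=0.0))
    rows = {}
    for name, ss_eff, ss_err, df_eff, df_err, scores in (
        ("State", ss_a, ss_as, a - 1, (a - 1) * (n - 1), scores_a),
        ("Time", ss_b, ss_bs, b - 1, (b - 1) * (n - 1), scores_b),
        ("State:Time", ss_ab, ss_abs, (a - 1) * (b - 1),
         (a - 1) * (b - 1) * (n - 1), scores_ab),
    ):
        eps = _hf_epsilon(scores, ref_scale)
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            f = p = np.nan
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, df_eff * eps, df_err * eps))
        rows[name] = (ss_eff, df_eff * eps, df_err * eps, ms_eff, ms_err, f, p, eps)

    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["ss", "df_num", "df_den", "ms", "ms_error", "F", "p", "epsilon_hf"],
    )
    table.attrs["ss_subjects"] = float(ss_subj)
    table.attrs["ss_total"] = float(ss_tot)
    return RmAnovaTable(table=table)
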
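"""Attribute taxa to temporal scales and summarize resilience attributes.

Each significant canonical axis is one temporal scale.  A taxon belongs to
the scale whose modelled pattern (lc scores) its *raw* biovolume series
tracks most strongly by Spearman rank correlation; taxa correlating with no
significant axis are *stochastic* — their dynamics carry no detectable shared
temporal structure.  The per-axis taxon counts quantify within-scale
redundancy, the number of significant axes the cross-scale structure, and the
stochastic fraction the noise-dominated component of the community.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CommunityTimeSeries,
    RDAModel,
    ResilienceSummary,
    ScaleAttribution,
    ValidationError,
    _round_half_away,
)

logger = logging.getLogger(__name__)


def attribute_species(
    cts: CommunityTimeSeries,
    model: RDAModel,
    alpha_species: float = 0.05,
) -> ScaleAttribution:
    """Assign every taxon to one significant axis or to the stochastic set.

    For each taxon and each significant axis, Spearman's rho and its
    two-sided p are computed between the raw biovolume series and the axis
    lc scores.  A taxon joins the axis with the largest |rho| among those
    with p <= ``alpha_species``; ties go to the lower-numbered (slower)
    axis.  Constant series (rho undefined) are stochastic.  The per-axis
    sets plus the stochastic set always partition the taxon list.
    """
    k = model.n_significant_axes
    if k < 1:
        raise ValidationError("model has no significant axis; all taxa stochastic")
    per_axis: list[list[str]] = [[] for _ in range(k)]
    stochastic: list[str] = []
    lc = model.lc_scores[:, :k]
    for j, taxon in enumerate(cts.taxa):
        y = cts.biovolume[:, j]
        if np.ptp(y) == 0:
            logger.info("taxon %r constant: forced stochastic", taxon)
            stochastic.append(taxon)
            continue
        best_axis, best_abs = -1, 0.0
        for a in range(k):
            rho, p = stats.spearmanr(y, lc[:, a])
            if np.isnan(rho) or p > alpha_species:
                continue
            if abs(rho) > best_abs + 1e-12:
                best_axis, best_abs = a, abs(rho)
        if best_axis < 0:
            stochastic.append(taxon)
        else:
            per_axis[best_axis].append(taxon)
    return ScaleAttribution(
        per_axis_species=per_axis,
        stochastic_species=stochastic,
        total=cts.n_taxa,
    )


def count_stochastic(total: int, per_axis_counts: list[int]) -> int:
    """Taxa on no axis: total minus the sum of per-axis counts."""
    n = total - sum(per_axis_counts)
    if n < 0:
        raise ValidationError("per-axis counts exceed the total")
    return n


def attribution_from_counts(
    total: int, per_axis_counts: list[int]
) -> ScaleAttribution:
    """Build an attribution from printed per-axis counts (placeholder labels).

    Useful for re-deriving stochastic counts and percentage columns from a
    published table where only the counts are available.
    """
    per_axis = [
        [f"axis{a + 1}_taxon{i + 1}" for i in range(c)]
        for a, c in enumerate(per_axis_counts)
    ]
    n_stoch = count_stochastic(total, per_axis_counts)
    stochastic = [f"stochastic_taxon{i + 1}" for i in range(n_stoch)]
    return ScaleAttribution(
        per_axis_species=per_axis, stochastic_species=stochastic, total=total
    )


def summarize_resilience(
    entries: list[tuple[str, str, RDAModel | None, ScaleAttribution | None]],
) -> pd.DataFrame:
    """One resilience-attribute row per (site, state) fitted model.

    ``entries`` holds ``(site, state, model, attribution)``; a None model
    (global test non-significant) yields n_scales = 0 and a fully stochastic
    community.  Columns: site, state, n_scales, within_scale_richness
    (comma-joined counts), stochastic_pct, model_adj_r2.
    """
    if not entries:
        raise ValidationError("need at least one fitted site x state")
    rows = []
    for site, state, model, attr in entries:
        if model is None or attr is None:
            summ = ResilienceSummary(
                site=site, state=state, n_scales=0, within_scale_richness=[],
                stochastic_fraction=100.0,
                model_adj_r2=float("nan") if model is None else model.adj_r2,
            )
        else:
            summ = ResilienceSummary(
                site=site,
                state=state,
                n_scales=model.n_significant_axes,
                within_scale_richness=attr.counts,
                stochastic_fraction=float(attr.percentages[-1]),
                model_adj_r2=model.adj_r2,
            )
        rows.append(
            {
                "site": summ.site,
                "state": summ.state,
                "n_scales": summ.n_scales,
                "within_scale_richness": ",".join(map(str, summ.within_scale_richness)),
                "stochastic_pct": summ.stochastic_fraction,
                "model_adj_r2": summ.model_adj_r2,
            }
        )
    return pd.DataFrame(rows)


def compare_states(
    summary: pd.DataFrame, state_a: str, state_b: str
) -> pd.DataFrame:
    """Paired per-site deltas (state_a minus state_b) of the key attributes."""
    a = summary[summary.state == state_a].set_index("site")
    b = summary[summary.state == state_b].set_index("site")
    sites = a.index.intersection(b.index)
    return pd.DataFrame(
        {
            "site": sites,
            "delta_n_scales": (a.loc[sites, "n_scales"] - b.loc[sites, "n_scales"]).to_numpy(),
            "delta_stochastic_pct": (
                a.loc[sites, "stochastic_pct"] - b.loc[sites, "stochastic_pct"]
            ).to_numpy(),
            "delta_adj_r2": (
                a.loc[sites, "model_adj_r2"] - b.loc[sites, "model_adj_r2"]
            ).to_numpy(),
        }
    )


def attribution_table(
    attributions: dict[tuple[str, str], ScaleAttribution]
) -> pd.DataFrame:
    """Published-style summary: rows = RDA 1..k, Stochastic, Total; cells = 'count(pct)'."""
    max_axes = max(len(a.per_axis_species) for a in attributions.values())
    index = [f"RDA {i + 1}" for i in range(max_axes)] + ["Stochastic", "Total"]
    table = {}
    for (site, state), attr in attributions.items():
        col = []
        pct = attr.percentages
        for i in range(max_axes):
            if i < len(attr.per_axis_species):
                col.append(f"{attr.counts[i]}({pct[i]})")
            else:
                col.append("---")
        col.append(f"{attr.stochastic_count}({pct[-1]})")
        col.append(str(attr.total))
        table[f"{site} {state}"] = col
    return pd.DataFrame(table, index=index)


def percentage_of_total(count: int, total: int) -> int:
    """Integer percentage, rounded half away from zero."""
    return _round_half_away(100.0 * count / total)
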
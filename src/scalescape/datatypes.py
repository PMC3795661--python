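"""Domain containers for community time series, drivers, and run configuration.

A *community time series* is a wide matrix of biovolume (mm^3 L^-1) with one
row per equidistant monthly time step and one column per taxon, observed at a
single site within a single hydrological state.  A *driver series* is the
univariate environmental record (here: flooded area, ha) used to delimit
states.  All downstream stages consume these two containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CommunityTimeSeries:
    """Taxa-by-time biovolume matrix for one site and one state window.

    Parameters
    ----------
    site_id, state_id
        Free-form labels (e.g. ``"MM"``, ``"wet"``).
    times
        Strictly increasing, equidistant integer month indices (1-based
        within a window).
    taxa
        Unique taxon labels, one per column of ``biovolume``.
    biovolume
        ``(n_time, n_taxa)`` array of non-negative biovolume.
    """

    site_id: str
    state_id: str
    times: np.ndarray
    taxa: list[str]
    biovolume: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.biovolume = np.asarray(self.biovolume, dtype=float)
        self.taxa = list(self.taxa)
        self.validate()

    # -- structural invariants ------------------------------------------------
    def validate(self) -> None:
        if self.times.ndim != 1 or len(self.times) < 3:
            raise ValidationError(
                f"need at least 3 time steps, got {len(self.times)}"
            )
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            i = int(np.argmax(steps <= 0))
            raise ValidationError(
                f"times not strictly increasing at step "
                f"{self.times[i]}->{self.times[i + 1]}"
            )
        if len(set(steps.tolist())) > 1:
            expected = steps[0]
            i = int(np.argmax(steps != expected))
            raise ValidationError(
                f"times not equidistant: gap {self.times[i]}->{self.times[i + 1]} "
                f"is {steps[i]}, expected {expected}"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        if self.biovolume.shape != (len(self.times), len(self.taxa)):
            raise ValidationError(
                f"biovolume shape {self.biovolume.shape} does not match "
                f"{len(self.times)} times x {len(self.taxa)} taxa"
            )
        if np.any(self.biovolume < 0):
            i, j = np.argwhere(self.biovolume < 0)[0]
            raise ValidationError(
                f"negative biovolume at time {self.times[i]}, taxon "
                f"{self.taxa[j]!r}: {self.biovolume[i, j]}"
            )
        if not np.all(np.isfinite(self.biovolume)):
            raise ValidationError("non-finite biovolume values present")

    @property
    def n_time(self) -> int:
        return len(self.times)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class DriverSeries:
    """Univariate driver record (e.g. flooded area in ha) on monthly steps."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-d and equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("driver values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AnalysisConfig:
    """Run configuration: significance levels, permutation counts, seeds.

    ``stars_*`` parameters control the sequential t-test regime detector:
    ``stars_cutoff_length`` is the minimum regime length l (months),
    ``stars_alpha`` the two-sided test level, and ``stars_huber`` the Huber
    tuning constant in units of the within-regime standard deviation.
    """

    alpha_axis: float = 0.05
    alpha_species: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    stars_cutoff_length: int = 12
    stars_alpha: float = 0.05
    stars_huber: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_axis", "alpha_species", "stars_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {a}")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if self.stars_cutoff_length < 2:
            raise ValidationError("stars_cutoff_length must be >= 2")
        if self.stars_huber <= 0:
            raise ValidationError("stars_huber must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RegimeShiftResult:
    """Output of the sequential t-test regime detector.

    ``shift_indices`` are 1-based time indices where a new regime starts;
    ``rsi`` maps each tested candidate index to its (signed) regime shift
    index, positive for confirmed shifts.
    """

    shift_indices: list[int]
    regime_means: list[float]
    rsi: dict[int, float]
    params: tuple[int, float, float]

    @property
    def n_regimes(self) -> int:
        return len(self.shift_indices) + 1


@dataclass
class AEMBasis:
    """Temporal eigenfunctions derived from the directed linear time graph."""

    n_time: int
    incidence: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    retained: np.ndarray

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_eigenfunctions(self) -> np.ndarray:
        """Columns with positive temporal autocorrelation, slow to fast."""
        return self.eigenfunctions[:, self.retained]


@dataclass
class RDAModel:
    """A fitted redundancy-analysis time-series model.

    ``lc_scores`` are the linear-combination site (time) scores: exact linear
    combinations of the selected predictors, one column per canonical axis.
    ``axis_pvalues`` holds sequential permutation p-values; axes after the
    first non-significant one are untested (NaN).
    """

    selected: list[int]
    coefficients: np.ndarray
    canonical_eigenvalues: np.ndarray
    lc_scores: np.ndarray
    species_scores: np.ndarray
    r2: float
    adj_r2: float
    axis_pvalues: np.ndarray = field(default=None)
    axis_adj_r2: np.ndarray = field(default=None)
    n_perm: int = 0
    seed: int = 0

    @property
    def n_axes(self) -> int:
        return self.lc_scores.shape[1]

    @property
    def n_significant_axes(self) -> int:
        """Leading axes judged significant by the sequential permutation test."""
        if self.axis_pvalues is None:
            return 0
        sig = 0
        for p in self.axis_pvalues:
            if np.isnan(p) or p > self._alpha_used:
                break
            sig += 1
        return sig

    _alpha_used: float = 0.05


@dataclass
class ScaleAttribution:
    """Partition of the taxon set across significant axes plus a stochastic set."""

    per_axis_species: list[list[str]]
    stochastic_species: list[str]
    total: int

    @property
    def counts(self) -> list[int]:
        return [len(s) for s in self.per_axis_species]

    @property
    def stochastic_count(self) -> int:
        return len(self.stochastic_species)

    @property
    def percentages(self) -> list[int]:
        """Per-axis then stochastic percentages of the total, integer-rounded."""
        return [
            _round_half_away(100.0 * c / self.total)
            for c in self.counts + [self.stochastic_count]
        ]


def _round_half_away(x: float) -> int:
    """Round half away from zero (5.5 -> 6), the table convention used here."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ResilienceSummary:
    """Per site-and-state resilience attributes from one fitted model."""

    site: str
    state: str
    n_scales: int
    within_scale_richness: list[int]
    stochastic_fraction: float
    model_adj_r2: float

    def __post_init__(self) -> None:
        if self.n_scales != len(self.within_scale_richness):
            raise ValidationError(
                "n_scales must equal the length of within_scale_richness"
            )
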
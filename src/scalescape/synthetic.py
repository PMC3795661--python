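"""Synthetic community and driver series with planted multi-scale structure.

The generator emulates the statistical structure the analysis assumes: a
small number of taxon groups whose log-biovolume fluctuates sinusoidally at
shared periods (with taxon-specific phases kept coherent within a group), a
complement of "stochastic" taxa whose log-biovolume is pure noise with the
same marginal variance as the signal taxa (so they are separable only by
their lack of shared temporal structure, not by variance), and a driver
series combining within-year seasonality with a supraseasonal step change.
Biovolume is the exponential of the log-scale signal, hence strictly
positive and right-skewed, as real biovolume data are.

Defaults describe a 24-month window with three planted scales (periods 24,
12 and 6 months) carried by 8 + 6 + 4 taxa plus 20 stochastic taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import CommunityTimeSeries, DriverSeries, ValidationError

#: within-group phase dispersion (radians); keeps a group on one common axis
PHASE_SPREAD = np.pi / 8


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    taxon_scale: list[str]          # per-taxon scale label ("scale1".. or "stochastic")
    scale_periods: list[float]      # months per planted scale
    shift_point: int | None         # planted regime-shift index (driver only)
    seed: int


def generate_community(
    n_time: int = 24,
    scale_periods: tuple[float, ...] = (24.0, 12.0, 6.0),
    species_per_scale: tuple[int, ...] = (8, 6, 4),
    n_stochastic: int = 20,
    amplitude: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
    site_id: str = "synthetic",
    state_id: str = "wet",
) -> tuple[CommunityTimeSeries, SyntheticTruth]:
    """Generate a community with taxon groups at planted temporal scales.

    Taxon j in scale group g has log-biovolume
    ``baseline_j + amplitude * sin(2*pi*t/period_g + phase_j) + N(0, noise_sd)``
    with group-coherent phases; stochastic taxa get pure Gaussian noise whose
    standard deviation matches the signal taxa's marginal spread
    ``sqrt(amplitude^2/2 + noise_sd^2)``.  Biovolume is the exponential of
    the log-scale series.  A fixed seed reproduces the output bit for bit.
    """
    if len(scale_periods) != len(species_per_scale):
        raise ValidationError("scale_periods and species_per_scale lengths differ")
    if any(p <= 0 for p in scale_periods):
        raise ValidationError("periods must be positive")
    if any(p < 2 or p > n_time for p in scale_periods):
        raise ValidationError("periods must lie in [2, n_time]")
    if scale_periods and n_time < 2 * max(scale_periods):
        warnings.warn(
            "n_time < 2 * max period: the slowest scale is weakly identified",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    t = np.arange(1, n_time + 1, dtype=float)
    cols, labels = [], []
    for g, (period, n_sp) in enumerate(zip(scale_periods, species_per_scale)):
        group_phase = rng.uniform(0, 2 * np.pi)
        for _ in range(n_sp):
            phase = group_phase + rng.uniform(-PHASE_SPREAD, PHASE_SPREAD)
            baseline = rng.normal(0.0, 0.5)
            log_y = (
                baseline
                + amplitude * np.sin(2 * np.pi * t / period + phase)
                + rng.normal(0.0, noise_sd, n_time)
            )
            cols.append(np.exp(log_y))
            labels.append(f"scale{g + 1}")
    sd_match = np.sqrt(amplitude**2 / 2 + noise_sd**2)
    for _ in range(n_stochastic):
        baseline = rng.normal(0.0, 0.5)
        cols.append(np.exp(baseline + rng.normal(0.0, sd_match, n_time)))
        labels.append("stochastic")
    taxa = [f"taxon_{i + 1:03d}" for i in range(len(cols))]
    cts = CommunityTimeSeries(
        site_id=site_id,
        state_id=state_id,
        times=np.arange(1, n_time + 1),
        taxa=taxa,
        biovolume=np.column_stack(cols),
    )
    truth = SyntheticTruth(
        taxon_scale=labels,
        scale_periods=list(scale_periods),
        shift_point=None,
        seed=seed,
    )
    return cts, truth


def generate_driver(
    n_time: int = 84,
    seasonal_amplitude: float = 1.0,
    step_time: int = 43,
    step_size: float = 5.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    base: float = 10.0,
) -> tuple[DriverSeries, SyntheticTruth]:
    """Generate a driver with seasonality plus a supraseasonal step change.

    ``value_t = base + seasonal_amplitude*sin(2*pi*t/12) +
    step_size*1[t >= step_time] + N(0, noise_sd)``.  The default emulates a
    seven-year monthly flooded-area record whose step (wet -> dry would be a
    negative ``step_size``) dwarfs the seasonal cycle.
    """
    if not 1 < step_time <= n_time:
        raise ValidationError("step_time must satisfy 1 < step_time <= n_time")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    t = np.arange(1, n_time + 1, dtype=float)
    values = (
        base
        + seasonal_amplitude * np.sin(2 * np.pi * t / 12)
        + step_size * (t >= step_time)
        + rng.normal(0.0, noise_sd, n_time)
    )
    driver = DriverSeries(times=np.arange(1, n_time + 1), values=values)
    truth = SyntheticTruth(
        taxon_scale=[], scale_periods=[], shift_point=step_time, seed=seed
    )
    return driver, truth


def two_state_preset(seed: int = 0, n_sites: int = 3):
    """A study-shaped dataset: per site, a wet window with three planted
    scales and a dry window with two scales and more stochastic taxa, plus a
    driver whose downward step separates the states.

    Returns ``(communities, truths, driver, driver_truth)`` where
    ``communities`` maps ``(site, state)`` to a CommunityTimeSeries.
    """
    root = np.random.SeedSequence(seed)
    site_seeds = root.spawn(n_sites + 1)
    communities, truths = {}, {}
    sites = ["S1", "S2", "S3", "S4", "S5"][:n_sites]
    for site, ss in zip(sites, site_seeds):
        wet_seed, dry_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
        cts_w, tr_w = generate_community(
            seed=wet_seed, site_id=site, state_id="wet"
        )
        cts_d, tr_d = generate_community(
            scale_periods=(24.0, 12.0),
            species_per_scale=(7, 5),
            n_stochastic=35,
            seed=dry_seed,
            site_id=site,
            state_id="dry",
        )
        communities[(site, "wet")] = cts_w
        communities[(site, "dry")] = cts_d
        truths[(site, "wet")] = tr_w
        truths[(site, "dry")] = tr_d
    drv_seed = int(site_seeds[-1].generate_state(1)[0] % (2**31 - 1))
    driver, drv_truth = generate_driver(seed=drv_seed, step_size=-5.0)
    return communities, truths, driver, drv_truth
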
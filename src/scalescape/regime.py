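"""Sequential t-test analysis of regime shifts (STARS) on a univariate driver.

The detector scans the series once.  A critical difference
``diff = t_crit(2l-2, alpha) * sqrt(2 * sigma_l^2 / l)`` is derived from the
average variance ``sigma_l^2`` of consecutive l-length windows.  Any new
observation outside the current regime mean +/- diff opens a candidate shift;
a regime shift index (RSI) — the cumulative sum of normalized, Huber-weighted
exceedances over the next l points — confirms the candidate if it stays
positive, otherwise the point is absorbed into the current regime.  Regime
means are Huber-weighted so single outliers do not drag them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import AnalysisConfig, DriverSeries, RegimeShiftResult, ValidationError


def _huber_weights(dev: np.ndarray, sigma: float, huber: float) -> np.ndarray:
    """Down-weight deviations beyond huber*sigma proportionally."""
    if sigma <= 0:
        return np.ones_like(dev)
    z = np.abs(dev) / sigma
    with np.errstate(divide="ignore"):
        w = np.where(z > huber, huber / z, 1.0)
    return w


def _huber_mean(x: np.ndarray, sigma: float, huber: float, n_iter: int = 3) -> float:
    """Huber-weighted mean, iterated a few times from the plain mean."""
    m = float(np.mean(x))
    for _ in range(n_iter):
        w = _huber_weights(x - m, sigma, huber)
        m = float(np.sum(w * x) / np.sum(w))
    return m


def detect_regimes(series: DriverSeries, config: AnalysisConfig) -> RegimeShiftResult:
    """Run the sequential t-test shift detector over a driver series.

    Returns shift indices in the units of ``series.times`` (a shift index is
    the first time step of the new regime), the Huber-weighted mean of each
    regime, and the RSI of every tested candidate (negative = rejected).
    """
    x = series.values
    n = len(x)
    l = config.stars_cutoff_length
    alpha = config.stars_alpha
    huber = config.stars_huber
    if n < 2 * l:
        raise ValidationError(f"series length {n} < 2*l = {2 * l}")

    # average within-window variance over all consecutive windows of length l
    win_vars = np.array([np.var(x[i : i + l], ddof=1) for i in range(n - l + 1)])
    sigma2 = float(win_vars.mean())
    sigma = np.sqrt(sigma2)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=2 * l - 2)
    diff = t_crit * np.sqrt(2.0 * sigma2 / l)

    shifts: list[int] = []  # 0-based positions, converted on return
    rsi_trace: dict[int, float] = {}
    regime_starts = [0]
    cur_mean = _huber_mean(x[:l], sigma, huber)

    t = l
    while t < n:
        dev = x[t] - cur_mean
        if abs(dev) <= diff:
            cur_mean = _huber_mean(x[regime_starts[-1] : t + 1], sigma, huber)
            t += 1
            continue
        # candidate shift at t: accumulate RSI over the next l points; a
        # candidate too close to the series end cannot complete the
        # sequential test and is absorbed (it would at best be tentative)
        if t + l > n:
            cur_mean = _huber_mean(x[regime_starts[-1] : t + 1], sigma, huber)
            t += 1
            continue
        sign = 1.0 if dev > 0 else -1.0
        level = cur_mean + sign * diff
        rsi = 0.0
        confirmed = True
        for j in range(t, min(t + l, n)):
            d = sign * (x[j] - level)
            w = _huber_weights(np.array([d]), sigma, huber)[0]
            rsi += (w * d) / (sigma * l) if sigma > 0 else d
            if rsi < 0:
                confirmed = False
                break
        # sign-adjusted accumulation: positive iff the candidate is confirmed
        rsi_trace[int(series.times[t])] = rsi
        if confirmed:
            shifts.append(t)
            regime_starts.append(t)
            cur_mean = _huber_mean(x[t : min(t + l, n)], sigma, huber)
        else:
            cur_mean = _huber_mean(x[regime_starts[-1] : t + 1], sigma, huber)
        t += 1

    bounds = regime_starts + [n]
    regime_means = [
        _huber_mean(x[a:b], sigma, huber) for a, b in zip(bounds, bounds[1:])
    ]
    return RegimeShiftResult(
        shift_indices=[int(series.times[s]) for s in shifts],
        regime_means=regime_means,
        rsi=rsi_trace,
        params=(l, alpha, huber),
    )


def states_from_regimes(
    result: RegimeShiftResult,
    series: DriverSeries,
    labels: list[str],
) -> list[tuple[int, int, str]]:
    """Turn detected regimes into contiguous ``(start, end, label)`` windows.

    One label per regime, in temporal order; the windows tile the full
    extent of the driver series and feed straight into ``split_by_state``.
    """
    if len(labels) != result.n_regimes:
        raise ValidationError(
            f"{len(labels)} labels for {result.n_regimes} regimes"
        )
    starts = [int(series.times[0])] + list(result.shift_indices)
    ends = [s - 1 for s in result.shift_indices] + [int(series.times[-1])]
    return [(s, e, lab) for s, e, lab in zip(starts, ends, labels)]
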
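"""Readers and writers for community tables, driver series, and configuration.

Tables are plain CSV (UTF-8, decimal point).  The wide dialect has the time
index in the first column and one column per taxon; the long dialect has
columns ``(time, taxon, biovolume)`` and lists only the cells it needs —
missing (time, taxon) pairs are filled with zero on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    CommunityTimeSeries,
    DriverSeries,
    ValidationError,
)

logger = logging.getLogger(__name__)


def read_community_table(
    path: str | Path,
    dialect: str = "wide",
    site_id: str = "site",
    state_id: str = "state",
) -> CommunityTimeSeries:
    """Read a community biovolume table from CSV.

    Parameters
    ----------
    dialect
        ``"wide"``: first column is the time index, remaining columns are
        taxa.  ``"long"``: columns ``time, taxon, biovolume``; unlisted
        (time, taxon) cells become zero.
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        times = df.iloc[:, 0].to_numpy()
        taxa = list(df.columns[1:])
        mat = df.iloc[:, 1:].to_numpy(dtype=float)
    elif dialect == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        expected = {"time", "taxon", "biovolume"}
        if not expected.issubset(df.columns):
            raise ValidationError(
                f"long dialect needs columns {sorted(expected)}, "
                f"got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["time", "taxon"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate (time, taxon) cell: ({row['time']}, {row['taxon']!r})"
            )
        wide = (
            df.pivot(index="time", columns="taxon", values="biovolume")
            .fillna(0.0)
            .sort_index()
        )
        times = wide.index.to_numpy()
        taxa = list(wide.columns)
        mat = wide.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return CommunityTimeSeries(
        site_id=site_id, state_id=state_id, times=times, taxa=taxa, biovolume=mat
    )


def write_community_table(cts: CommunityTimeSeries, path: str | Path) -> None:
    """Write a community table in the wide CSV dialect (round-trip exact)."""
    df = pd.DataFrame(cts.biovolume, columns=cts.taxa)
    df.insert(0, "time", cts.times)
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


def read_driver_series(path: str | Path) -> DriverSeries:
    """Read a two-column (time, value) driver CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError("driver table needs (time, value) columns")
    return DriverSeries(
        times=df.iloc[:, 0].to_numpy(), values=df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_driver_series(driver: DriverSeries, path: str | Path) -> None:
    pd.DataFrame({"time": driver.times, "value": driver.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_config(path: str | Path) -> AnalysisConfig:
    """Load a flat key-value YAML configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**raw)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def split_by_state(
    cts: CommunityTimeSeries,
    windows: list[tuple[int, int, str]],
) -> list[CommunityTimeSeries]:
    """Cut a series into per-state windows and drop taxa unobserved in each.

    Parameters
    ----------
    windows
        ``(start, end, state_label)`` with inclusive time bounds in the units
        of ``cts.times``.  Windows must not overlap and must lie inside the
        series.  Within each window, times are renumbered to 1-based month
        indices and all-zero taxon columns are dropped (they are unobserved
        in that state); drops are logged.
    """
    spans = sorted((int(s), int(e)) for s, e, _ in windows)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValidationError(
                f"overlapping windows: ({s1},{e1}) and ({s2},{e2})"
            )
    out = []
    for start, end, label in windows:
        mask = (cts.times >= start) & (cts.times <= end)
        if not mask.any():
            raise ValidationError(f"window ({start},{end}) selects no time steps")
        if start < cts.times.min() or end > cts.times.max():
            raise ValidationError(
                f"window ({start},{end}) extends outside the series "
                f"[{cts.times.min()},{cts.times.max()}]"
            )
        sub = cts.biovolume[mask]
        keep = sub.sum(axis=0) > 0
        dropped = [t for t, k in zip(cts.taxa, keep) if not k]
        if dropped:
            logger.info(
                "window (%s,%s,%s): dropping %d all-zero taxa: %s",
                start, end, label, len(dropped), dropped,
            )
        out.append(
            CommunityTimeSeries(
                site_id=cts.site_id,
                state_id=label,
                times=np.arange(1, int(mask.sum()) + 1),
                taxa=[t for t, k in zip(cts.taxa, keep) if k],
                biovolume=sub[:, keep],
            )
        )
    return out
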
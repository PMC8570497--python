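"""Tabular text I/O for time series.

Files are delimiter-separated text with a header naming each column and its
unit, e.g. ``time_ms<TAB>v_pre_mV``.  On disk the conventional units of the
field are used (ms, mV, nA); in memory everything is SI.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries, UNIT_SCALES

__all__ = ["read_timeseries", "write_timeseries", "read_table", "write_table"]

#: unit tag used on disk for each in-memory SI unit
_DISK_UNIT = {"V": "mV", "A": "nA", "S": "S", "dimensionless": "dimensionless"}
_DISK_SCALE = {"mV": 1e-3, "nA": 1e-9, "V": 1.0, "A": 1.0, "S": 1.0,
               "dimensionless": 1.0, "ms": 1e-3, "s": 1.0, "us": 1e-6}


def _split_unit(column: str) -> tuple[str, str]:
    name, _, unit = column.rpartition("_")
    if unit not in _DISK_SCALE:
        raise ValueError(f"unknown unit tag {unit!r} in column {column!r}")
    return name, unit


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("time column has fewer than 2 samples")
    ref = float(np.median(dt))
    bad = np.nonzero(np.abs(dt - ref) > 1e-9 * max(abs(ref), 1e-30))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform time base at index {i + 1}: step {dt[i]!r} vs {ref!r}"
        )
    if ref <= 0:
        raise ValueError("time column is not increasing")
    return ref


def write_timeseries(series: TimeSeries, path: str | Path, name: str = "signal") -> None:
    """Write a single series as two-column TSV (time_ms plus the signal)."""
    write_table({name: series}, path)


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a two-column file written by :func:`write_timeseries`."""
    table = read_table(path)
    if len(table) != 1:
        raise ValueError(f"{path} holds {len(table)} signal columns, expected 1")
    return next(iter(table.values()))


def write_table(series_map: dict[str, TimeSeries], path: str | Path) -> None:
    """Write aligned named series as one TSV (first column ``time_ms``)."""
    items = list(series_map.items())
    first = items[0][1]
    for _, s in items[1:]:
        if not first.same_base(s):
            raise ValueError("all series in one table must share a time base")
    data = {"time_ms": first.times / 1e-3}
    for name, s in items:
        disk_unit = _DISK_UNIT.get(s.unit, s.unit)
        data[f"{name}_{disk_unit}"] = s.values / _DISK_SCALE[disk_unit]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> dict[str, TimeSeries]:
    """Read a TSV written by :func:`write_table`; returns {name: TimeSeries}."""
    df = pd.read_csv(path, sep="\t")
    tname, tunit = _split_unit(df.columns[0])
    if tname != "time":
        raise ValueError(f"first column of {path} must be time, got {df.columns[0]!r}")
    t = df.iloc[:, 0].to_numpy(dtype=float) * _DISK_SCALE[tunit]
    dt = _check_uniform(t)
    out: dict[str, TimeSeries] = {}
    for col in df.columns[1:]:
        name, unit = _split_unit(col)
        si_unit = {"mV": "V", "nA": "A"}.get(unit, unit)
        if si_unit not in UNIT_SCALES:
            raise ValueError(f"unknown unit tag {unit!r} in column {col!r}")
        out[name] = TimeSeries(
            df[col].to_numpy(dtype=float) * _DISK_SCALE[unit],
            dt=dt, t0=float(t[0]), unit=si_unit,
        )
    return out
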
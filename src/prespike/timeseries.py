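"""Uniformly sampled time series, the carrier for all signals in the package.

Internally everything is SI (volts, amperes, seconds).  The unit tag records
what the samples mean; conversion to/from the conventional electrophysiology
units (mV, nA, ms) happens only at the file-format boundary (:mod:`prespike.io`)
and in the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeries"]

#: SI scale factors for recognized unit tags (tag -> multiply-by to get SI).
UNIT_SCALES = {
    "V": 1.0,
    "mV": 1e-3,
    "A": 1.0,
    "nA": 1e-9,
    "pA": 1e-12,
    "S": 1.0,
    "dimensionless": 1.0,
}


@dataclass
class TimeSeries:
    """A uniformly sampled real signal.

    Parameters
    ----------
    values
        Sample values in SI units of ``unit``.
    dt
        Sample interval in seconds, > 0.
    t0
        Time of the first sample in seconds.
    unit
        Physical-unit tag: ``"V"``, ``"A"``, ``"S"`` or ``"dimensionless"``.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("TimeSeries needs a 1-D array of at least 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("TimeSeries samples must all be finite")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    # -- helpers -----------------------------------------------------------
    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeSeries":
        """A copy of this series carrying new samples on the same time base."""
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)

    def copy(self) -> "TimeSeries":
        return replace(self, values=self.values.copy())

    def slice_time(self, t_start: float, t_end: float) -> "TimeSeries":
        """The sub-series with t_start <= t <= t_end (inclusive, sample-aligned)."""
        t = self.times
        mask = (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
        if mask.sum() < 2:
            raise ValueError("requested window contains fewer than 2 samples")
        i0 = int(np.argmax(mask))
        return TimeSeries(self.values[mask], self.dt, t0=t[i0], unit=self.unit)

    def same_base(self, other: "TimeSeries", rtol: float = 1e-9) -> bool:
        """Whether ``other`` shares this series' time base (t0, dt, length)."""
        return (
            len(self) == len(other)
            and abs(self.dt - other.dt) <= rtol * self.dt
            and abs(self.t0 - other.t0) <= rtol * max(self.dt, abs(self.t0) + self.dt)
        )


def require_aligned(*series: TimeSeries) -> None:
    """Raise ValueError unless all series share one time base."""
    first = series[0]
    for s in series[1:]:
        if not first.same_base(s):
            raise ValueError(
                "time series are not aligned: "
                f"(t0={first.t0}, dt={first.dt}, n={len(first)}) vs "
                f"(t0={s.t0}, dt={s.dt}, n={len(s)})"
            )
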
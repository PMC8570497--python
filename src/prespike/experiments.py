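"""Canonical in-silico experiments built from the lower-level modules.

The central one pairs two ODE runs of the calcium-only cleft model — one with
zero cleft resistance (the cleft potential pinned at 0) and one with a finite
cleft conductance — to quantify how the cleft potential feeds back on the
presynaptic calcium current: how far the current's peak is reduced, and how
much later its onset and peak occur.  The calcium conductance density is
calibrated so the zero-resistance run elicits a stated peak current, which
makes the paired comparison independent of the surrogate AP's absolute
activation efficacy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import builtin_channel
from .circuit import CircuitParams, simulate_synapse
from .estimation import _parabolic_refine
from .synthetic import APShape, make_action_potential
from .timeseries import TimeSeries

__all__ = ["CalciumCleftResult", "calibrate_calcium_density",
           "calcium_cleft_experiment"]


def _surrogate_ap(fwhm: float, amplitude: float, v_rest: float,
                  dt: float) -> TimeSeries:
    shape = APShape(v_rest=v_rest, amplitude=amplitude, fwhm=fwhm,
                    t_peak=3 * fwhm)
    return make_action_potential(shape, dt=dt, duration=shape.t_peak + 8 * fwhm)


def calibrate_calcium_density(v_pre: TimeSeries, target_peak: float = -2e-9,
                              area: float = 1000.0) -> float:
    """Calcium density (nS/um^2) eliciting ``target_peak`` at zero cleft
    resistance.

    With the cleft potential pinned at zero there is no feedback, so the
    current is exactly linear in the maximal conductance: one probe run
    determines the density.
    """
    probe = builtin_channel("ca2", density=1.0, area=area)
    params = CircuitParams.calyx(g_cl=np.inf, c_cl=10e-12)
    sim = simulate_synapse(v_pre, [probe], params, max_step=v_pre.dt * 4)
    peak_per_unit = sim.channel_currents["ca2"].values.min()
    if peak_per_unit >= 0:
        raise RuntimeError("probe run produced no inward calcium current")
    return float(target_peak / peak_per_unit)


def _extreme_time_value(x: np.ndarray, dt: float, minimum: bool = True
                        ) -> tuple[float, float]:
    i = int(np.argmin(x) if minimum else np.argmax(x))
    return _parabolic_refine(x, i, dt, 0.0)


def _onset_time(x: np.ndarray, dt: float, fraction: float) -> float:
    """First crossing of ``fraction`` of the (inward, negative) peak."""
    thr = x.min() * fraction
    i = int(np.argmax(x < thr))
    if i == 0:
        return 0.0
    return (i - 1) * dt + (thr - x[i - 1]) / (x[i] - x[i - 1]) * dt


@dataclass(frozen=True)
class CalciumCleftResult:
    """Paired zero-resistance / finite-g_cl calcium-current comparison."""

    density: float  # nS/um^2 (calibrated)
    v_cl_max: float  # V, finite-g_cl run
    v_cl_min: float  # V
    i_peak_free: float  # A, zero cleft resistance
    i_peak_cleft: float  # A, finite g_cl
    peak_reduction: float  # fraction: 1 - |cleft|/|free|
    peak_shift: float  # s, cleft peak time minus free peak time
    onset_shift: float  # s, threshold-crossing shift
    n_samples: int


def calcium_cleft_experiment(
    fwhm: float,
    amplitude: float = 0.120,
    v_rest: float = -0.080,
    g_cl: float = 0.67e-6,
    c_cl: float = 10e-12,
    target_peak: float = -2e-9,
    area: float = 1000.0,
    dt: float = 5e-6,
    onset_fraction: float = 0.1,
) -> CalciumCleftResult:
    """Quantify cleft-potential feedback on the calcium current for one AP.

    Runs the calcium-only model twice (zero cleft resistance, then the given
    ``g_cl``) with the density calibrated to ``target_peak`` at zero
    resistance, and reports the cleft-potential extrema plus the peak
    reduction and the peak-time and onset-time shifts of the current.
    """
    v_pre = _surrogate_ap(fwhm, amplitude, v_rest, dt)
    density = calibrate_calcium_density(v_pre, target_peak, area)
    ca = builtin_channel("ca2", density=density, area=area)
    free = simulate_synapse(v_pre, [ca],
                            CircuitParams.calyx(g_cl=np.inf, c_cl=c_cl),
                            max_step=dt * 4)
    cleft = simulate_synapse(v_pre, [ca],
                             CircuitParams.calyx(g_cl=g_cl, c_cl=c_cl),
                             max_step=dt * 4)
    i_free = free.channel_currents["ca2"].values
    i_cleft = cleft.channel_currents["ca2"].values
    t_free, pk_free = _extreme_time_value(i_free, dt)
    t_cleft, pk_cleft = _extreme_time_value(i_cleft, dt)
    return CalciumCleftResult(
        density=density,
        v_cl_max=float(cleft.v_cl.values.max()),
        v_cl_min=float(cleft.v_cl.values.min()),
        i_peak_free=pk_free,
        i_peak_cleft=pk_cleft,
        peak_reduction=1.0 - abs(pk_cleft) / abs(pk_free),
        peak_shift=t_cleft - t_free,
        onset_shift=_onset_time(i_cleft, dt, onset_fraction)
        - _onset_time(i_free, dt, onset_fraction),
        n_samples=len(v_pre),
    )
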
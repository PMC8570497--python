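"""Lumped electrical model of the synaptic cleft and the prespike.

The cleft is one equipotential compartment at potential ``v_cl`` (relative to
the grounded interstitial space), bounded by the presynaptic cleft-facing
capacitance ``c_pre``, the postsynaptic cleft-facing capacitance ``c_syn``,
and a leak conductance to ground ``g_cl``.  Currents entering the cleft
(presynaptic capacitive current plus voltage-gated currents) leave either
capacitively across the membranes or resistively through ``g_cl``; which route
dominates sets the shape of the prespike recorded in the postsynaptic cell.

Two layers are provided:

* closed forms for the two limiting dissipation regimes ("capacitive" —
  cleft resistance high, v_cl integrates i_enter; "resistive" — cleft highly
  conductive, v_cl tracks i_enter/g_cl), which assume the postsynaptic side
  is voltage clamped so g_syn and the non-cleft compartment drop out;
* a full ODE simulator in which cleft-facing Markov channels sense
  ``v_pre - v_cl``, so gating feeds back on the cleft potential.

All quantities are SI (V, A, S, F, s); channel rate constants are converted
at the boundary (the kinetics tables are in mV and 1/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.interpolate import CubicSpline

from .channels import ChannelSpec, open_probability, rate_matrix, steady_state_occupancy
from .timeseries import TimeSeries, require_aligned

__all__ = [
    "CircuitParams",
    "SimulationResult",
    "cleft_entering_current",
    "predict_cleft_potential",
    "predict_vc_prespike",
    "predict_calcium_prespike",
    "cc_prespike_from_current",
    "simulate_synapse",
]


@dataclass(frozen=True)
class CircuitParams:
    """Lumped capacitances and conductances of terminal, cleft and target cell.

    All SI.  ``c_syn``/``g_syn`` are the postsynaptic cleft-facing elements,
    ``c_post``/``g_post`` the whole-cell ones.  For the giant calyx-type
    synapse the pre- and postsynaptic cleft-facing capacitances are close to
    equal, so the cleft-facing capacitance ``c_cl`` is taken as ``c_syn`` and
    a symmetry check is available.
    """

    c_pre: float  # F
    c_syn: float  # F
    c_post: float  # F
    g_cl: float  # S (may be inf: zero cleft resistance)
    g_pre: float = 1e-9  # S
    g_syn: float = 1e-9  # S
    g_post: float = 4e-9  # S
    v_rest: float = -0.070  # V

    def __post_init__(self) -> None:
        for name in ("c_pre", "c_syn", "c_post"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.g_cl > 0:
            raise ValueError("g_cl must be > 0 (use inf for zero cleft resistance)")

    @property
    def c_cl(self) -> float:
        """Cleft-facing capacitance (postsynaptic side), F."""
        return self.c_syn

    @property
    def tau_cl(self) -> float:
        """Cleft time constant c_cl/g_cl, s (0 for infinite g_cl)."""
        return 0.0 if np.isinf(self.g_cl) else self.c_cl / self.g_cl

    def symmetric(self, rtol: float = 0.05) -> bool:
        """Whether c_pre and c_syn are equal within ``rtol``."""
        return abs(self.c_pre - self.c_syn) <= rtol * self.c_syn

    @classmethod
    def calyx(cls, *, g_cl: float = 1e-6, c_cl: float = 10e-12,
              c_post: float = 25e-12, g_post: float = 4e-9,
              v_rest: float = -0.070) -> "CircuitParams":
        """Canonical juvenile calyx-type parameter set (symmetric cleft)."""
        return cls(c_pre=c_cl, c_syn=c_cl, c_post=c_post,
                   g_cl=g_cl, g_post=g_post, v_rest=v_rest)


def _grad(values: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(values, dt, edge_order=2)


def cleft_entering_current(
    v_pre: TimeSeries,
    params: CircuitParams,
    ionic_currents: Sequence[TimeSeries] | None = None,
) -> TimeSeries:
    """Current entering the cleft: c_pre * dv_pre/dt plus any ionic currents.

    Inward membrane currents are negative throughout the package.
    """
    if v_pre.unit not in ("V", "dimensionless"):
        raise ValueError(f"v_pre must carry volts, got unit {v_pre.unit!r}")
    i = params.c_pre * _grad(v_pre.values, v_pre.dt)
    for ion in ionic_currents or ():
        require_aligned(v_pre, ion)
        if ion.unit not in ("A", "dimensionless"):
            raise ValueError(f"ionic current must carry amperes, got {ion.unit!r}")
        i = i + ion.values
    return v_pre.with_values(i, unit="A")


def predict_cleft_potential(
    i_enter: TimeSeries, params: CircuitParams, scenario: str
) -> TimeSeries:
    """Closed-form cleft potential for one limiting dissipation regime.

    ``capacitive``: v_cl = (c_pre + c_syn)^-1 * integral(i_enter) (zero at t0).
    ``resistive``:  v_cl = i_enter / g_cl, pointwise.
    """
    if scenario == "capacitive":
        v = cumulative_trapezoid(i_enter.values, dx=i_enter.dt, initial=0.0)
        v = v / (params.c_pre + params.c_syn)
    elif scenario == "resistive":
        v = np.zeros_like(i_enter.values) if np.isinf(params.g_cl) \
            else i_enter.values / params.g_cl
    else:
        raise ValueError(f"unknown scenario {scenario!r}; use 'capacitive' or 'resistive'")
    return i_enter.with_values(v, unit="V")


def predict_vc_prespike(
    v_pre: TimeSeries, params: CircuitParams, scenario: str
) -> TimeSeries:
    """Voltage-clamp prespike (the recorded current i_rec) from the AP alone.

    ``capacitive``: i_rec = -c_syn/(c_pre+c_syn) * i_enter, i.e. about half of
    i_enter for a symmetric cleft.
    ``resistive``:  i_rec = -(c_syn * c_pre / g_cl) * d2v_pre/dt2, which for a
    symmetric cleft is -g_cl * tau_cl^2 * d2v_pre/dt2.  The first peak is
    negative for a rising AP.
    """
    if scenario == "capacitive":
        i_enter = cleft_entering_current(v_pre, params)
        i = -(params.c_syn / (params.c_pre + params.c_syn)) * i_enter.values
    elif scenario == "resistive":
        if np.isinf(params.g_cl):
            i = np.zeros_like(v_pre.values)
        else:
            d2 = _grad(_grad(v_pre.values, v_pre.dt), v_pre.dt)
            i = -(params.c_syn * params.c_pre / params.g_cl) * d2
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return v_pre.with_values(i, unit="A")


def predict_calcium_prespike(
    i_ca: TimeSeries, params: CircuitParams, scenario: str
) -> TimeSeries:
    """Calcium component of the VC prespike (recorded current).

    ``capacitive``: i_rec = -i_ca (the inverted calcium current).
    ``resistive``:  i_rec = -tau_cl * di_ca/dt (inverted, scaled first
    derivative; tau_cl = c_syn/g_cl).
    """
    if scenario == "capacitive":
        i = -i_ca.values
    elif scenario == "resistive":
        tau = params.c_syn / params.g_cl if not np.isinf(params.g_cl) else 0.0
        i = -tau * _grad(i_ca.values, i_ca.dt)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return i_ca.with_values(i, unit="A")


def cc_prespike_from_current(i_rec: TimeSeries, params: CircuitParams) -> TimeSeries:
    """Current-clamp prespike: the postsynaptic RC response to -i_rec.

    Solves c_post dv/dt + g_post (v - v_rest) = -i_rec exactly per sample
    (zero-order-hold exponential update); gain 1/g_post, time constant
    c_post/g_post, baseline v_rest.
    """
    if params.g_post <= 0:
        raise ValueError("g_post must be positive for a current-clamp response")
    tau = params.c_post / params.g_post
    a = np.exp(-i_rec.dt / tau)
    drive = -i_rec.values / params.g_post  # steady-state deflection per sample
    v = np.empty_like(drive)
    dev = 0.0
    for n, d in enumerate(drive):
        v[n] = params.v_rest + dev
        dev = dev * a + d * (1.0 - a)
    return i_rec.with_values(v, unit="V")


@dataclass
class SimulationResult:
    """Output of :func:`simulate_synapse`; all series share the input base."""

    v_cl: TimeSeries
    v_post: TimeSeries
    i_rec: TimeSeries
    channel_currents: dict[str, TimeSeries]
    occupancies: dict[str, np.ndarray]  # kind -> (n_times, n_states)
    diagnostics: dict


def _rhs_factory(vp: CubicSpline, dvp: CubicSpline, params: CircuitParams,
                 specs: Sequence[ChannelSpec], i_inj: CubicSpline | None):
    c_cl, c_post = params.c_cl, params.c_post
    g_cl, g_post, v_rest = params.g_cl, params.g_post, params.v_rest
    inf_gcl = np.isinf(g_cl)
    denom = c_cl * (2.0 - c_cl / c_post)
    if abs(denom) < 1e-30:
        raise ValueError("singular coupling: c_post == c_cl/2 makes the 2x2 system degenerate")
    offsets = np.cumsum([2] + [s.n_states for s in specs])  # state layout

    # flattened transition bookkeeping for a vectorized master equation
    src, dst, a_arr, b_arr, state_of = [], [], [], [], []
    g_max_si = np.array([s.g_max * 1e-9 for s in specs])
    v_rev_si = np.array([s.v_reversal * 1e-3 for s in specs])
    open_idx = np.array([offsets[k] + s.open_state for k, s in enumerate(specs)],
                        dtype=int)
    squared = np.array([s.squared for s in specs])
    for k, spec in enumerate(specs):
        for tr in spec.transitions:
            src.append(offsets[k] + tr.source)
            dst.append(offsets[k] + tr.target)
            a_arr.append(tr.a)
            b_arr.append(tr.b)
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    a_arr = np.asarray(a_arr)
    b_arr = np.asarray(b_arr)

    def ionic_current(t: float, v_cl: float, y: np.ndarray) -> float:
        v_pre = vp(t)
        total = 0.0
        if specs:
            po = y[open_idx].copy()
            po[squared] = po[squared] ** 2
            total += float(np.sum(g_max_si * po * (v_pre - v_cl - v_rev_si)))
        if i_inj is not None:
            total += float(i_inj(t))
        return total

    def derivatives(t: float, y: np.ndarray) -> np.ndarray:
        v_cl, v_post = y[0], y[1]
        dy = np.zeros_like(y)
        i_ion = ionic_current(t, v_cl, y)
        if inf_gcl:
            dv_cl = 0.0
        else:
            dv_cl = (c_cl * dvp(t) - (c_cl * g_post / c_post) * (v_post - v_rest)
                     - g_cl * v_cl + i_ion) / denom
        dv_post = (c_cl * dv_cl - g_post * (v_post - v_rest)) / c_post
        dy[0], dy[1] = dv_cl, dv_post
        if src.size:
            v_eff_mv = (vp(t) - v_cl) * 1e3
            rates = a_arr * np.exp(np.clip(b_arr * v_eff_mv, -50.0, 50.0))
            flux = rates * y[src] * 1e3  # 1/ms -> 1/s
            np.subtract.at(dy, src, flux)
            np.add.at(dy, dst, flux)
        return dy

    return derivatives, ionic_current, offsets


def simulate_synapse(
    v_pre: TimeSeries,
    specs: Sequence[ChannelSpec],
    params: CircuitParams,
    *,
    i_injected: TimeSeries | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_step: float | None = None,
    method: str = "RK45",
) -> SimulationResult:
    """Integrate the coupled cleft/postsynaptic ODEs with channel feedback.

    State: (v_cl, v_post, occupancies of every channel).  The two derivative
    equations reference each other; they are linear in the derivatives and are
    eliminated algebraically at every step.  Channel rates are evaluated at
    ``v_pre - v_cl``.  ``v_pre`` (and any injected cleft current) is supplied
    to the adaptive integrator by cubic-spline interpolation.

    ``params.g_cl = inf`` is the zero-cleft-resistance limit: v_cl is pinned
    at 0 and the channels sense the raw AP.

    Returns the result sampled on the input time base; ``i_rec`` is the
    cleft-facing postsynaptic capacitive current c_cl * dv_cl/dt (the current
    a postsynaptic voltage-clamp amplifier records).

    ``method`` is any solve_ivp method; the default embedded Runge-Kutta 4/5
    mirrors the adaptive RKF integration the model was designed with, but the
    fast sodium deactivation near rest makes the homogeneous model stiff —
    pass ``"LSODA"`` there (trajectories agree to the requested tolerance).
    """
    t = v_pre.times
    vp = CubicSpline(t, v_pre.values)
    dvp = vp.derivative()
    inj = None
    if i_injected is not None:
        require_aligned(v_pre, i_injected)
        inj = CubicSpline(t, i_injected.values)

    rhs, ionic_current, offsets = _rhs_factory(vp, dvp, params, specs, inj)

    y0 = np.zeros(offsets[-1])
    y0[1] = params.v_rest
    v_eff0_mv = (v_pre.values[0] - 0.0) * 1e3
    for k, spec in enumerate(specs):
        y0[offsets[k]:offsets[k + 1]] = steady_state_occupancy(spec, v_eff0_mv).occupancies

    sol = solve_ivp(
        rhs, (t[0], t[-1]), y0, method=method, t_eval=t,
        rtol=rtol, atol=atol, max_step=max_step or np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    y = sol.y
    dv_cl = np.array([rhs(ti, y[:, i])[0] for i, ti in enumerate(t)])
    i_rec = params.c_cl * dv_cl

    currents: dict[str, TimeSeries] = {}
    occupancies: dict[str, np.ndarray] = {}
    for k, spec in enumerate(specs):
        p = y[offsets[k]:offsets[k + 1], :]
        # renormalize only for reporting; raw states are what was integrated
        p_norm = p / p.sum(axis=0, keepdims=True)
        po = p_norm[spec.open_state]
        if spec.squared:
            po = po ** 2
        i_k = spec.g_max * 1e-9 * po * (v_pre.values - y[0] - spec.v_reversal * 1e-3)
        currents[spec.kind] = v_pre.with_values(i_k, unit="A")
        occupancies[spec.kind] = p.T

    conservation_err = max(
        (np.abs(y[offsets[k]:offsets[k + 1], :].sum(axis=0) - 1.0).max()
         for k in range(len(specs))), default=0.0)
    return SimulationResult(
        v_cl=v_pre.with_values(y[0], unit="V"),
        v_post=v_pre.with_values(y[1], unit="V"),
        i_rec=v_pre.with_values(i_rec, unit="A"),
        channel_currents=currents,
        occupancies=occupancies,
        diagnostics={
            "n_steps": int(sol.t.size),
            "nfev": int(sol.nfev),
            "max_conservation_error": float(conservation_err),
            "success": bool(sol.success),
        },
    )
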
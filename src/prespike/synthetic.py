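"""Parametric presynaptic waveforms and forward-modeled paired recordings.

The published AP-waveform command used in the voltage-clamp experiments is
not available, so a smooth parametric surrogate is used: the product of two
logistic ramps with independent rise and decay time constants, scaled to a
requested amplitude and full width at half maximum.  The generator emulates
the study's protocols — AP-waveform trains (identical pulses, or with
per-pulse amplitude decay and broadening), a roughly Gaussian presynaptic
calcium current during repolarization, the P/5 scaled-stimulus protocol
(passive sweeps at one-fifth amplitude which elicit no calcium current), and
additive Gaussian recording noise with an optional EPSC contaminant — with
the ground-truth circuit parameters recorded alongside, so every downstream
estimator can be validated by round trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.signal import find_peaks

from . import io as tsio
from .circuit import (CircuitParams, cleft_entering_current, predict_calcium_prespike,
                      predict_vc_prespike, simulate_synapse)
from .timeseries import TimeSeries, require_aligned

__all__ = [
    "APShape",
    "TrainProtocol",
    "EPSCDescriptor",
    "RecordingSet",
    "make_action_potential",
    "make_ap_train",
    "make_calcium_current",
    "make_calcium_train",
    "synthesize_paired_recording",
    "write_recording_set",
    "read_recording_set",
]

#: default simulation / recording sample intervals (s)
SIM_DT = 5e-6
REC_DT = 20e-6


@dataclass(frozen=True)
class APShape:
    """Surrogate action-potential waveform parameters.

    ``asymmetry`` is the rise/decay time-constant ratio of the two logistic
    ramps (< 1: rise faster than decay, as for a real AP).  The default
    amplitude (120 mV from a -80 mV rest) is a configurable guess; only the
    FWHM of the waveforms used in the source experiments is known.
    """

    v_rest: float = -0.080  # V
    amplitude: float = 0.120  # V, peak minus rest
    fwhm: float = 0.5e-3  # s
    t_peak: float = 2e-3  # s
    asymmetry: float = 0.4

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if not self.asymmetry > 0:
            raise ValueError("asymmetry must be > 0")


@dataclass(frozen=True)
class TrainProtocol:
    """A stimulus train: count, interval, per-pulse amplitude/width factors."""

    n_stimuli: int = 45
    interval: float = 10e-3  # s (100 Hz)
    amplitude_decay: float = 1.0
    broadening: float = 1.0

    def __post_init__(self) -> None:
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if not self.interval > 0:
            raise ValueError("interval must be > 0")


@dataclass(frozen=True)
class EPSCDescriptor:
    """Difference-of-exponentials EPSC contaminant added to active sweeps.

    Starts ``delay`` after each calcium-current peak (release follows calcium
    influx rapidly); amplitude is negative (inward).
    """

    amplitude: float = -2e-9  # A
    delay: float = 0.3e-3  # s after the calcium-current peak
    tau_rise: float = 0.2e-3  # s
    tau_decay: float = 1.0e-3  # s


# ---------------------------------------------------------------------------
# surrogate AP waveform: product of two logistic ramps on a scaled time axis
# ---------------------------------------------------------------------------

def _logistic_product(u: np.ndarray | float, asym: float) -> np.ndarray | float:
    """Unnormalized pulse g(u) = sigma(u/asym) * sigma(-u)."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.clip(u / asym, -500, 500))) \
             / (1.0 + np.exp(np.clip(u, -500, 500)))


def _pulse_reference(asym: float) -> tuple[float, float, float]:
    """(u_peak, g_peak, fwhm_u) of the unit logistic-product pulse."""
    res = minimize_scalar(lambda u: -_logistic_product(u, asym),
                          bounds=(-50 * asym, 50), method="bounded",
                          options={"xatol": 1e-12})
    u_pk = float(res.x)
    g_pk = float(_logistic_product(u_pk, asym))
    half = g_pk / 2.0
    lo = brentq(lambda u: _logistic_product(u, asym) - half, u_pk - 100 * asym - 100, u_pk)
    hi = brentq(lambda u: _logistic_product(u, asym) - half, u_pk, u_pk + 200)
    return u_pk, g_pk, float(hi - lo)


def _pulse_values(t: np.ndarray, amplitude: float, fwhm: float, t_peak: float,
                  asym: float) -> np.ndarray:
    """Pulse (baseline 0, peak ``amplitude`` at ``t_peak``) on times ``t``."""
    if amplitude == 0.0:
        return np.zeros_like(t)
    u_pk, g_pk, fwhm_u = _pulse_reference(asym)
    s = fwhm / fwhm_u  # time scale
    u = (t - t_peak) / s + u_pk
    return amplitude * np.asarray(_logistic_product(u, asym)) / g_pk


def make_action_potential(shape: APShape, dt: float = SIM_DT,
                          duration: float | None = None) -> TimeSeries:
    """A single surrogate AP as a membrane-potential series (V).

    The waveform is smooth (twice differentiable), starts and ends at rest,
    peaks at ``shape.t_peak`` with the requested amplitude, and has the
    requested FWHM.  Raises if ``duration`` leaves less than five FWHM of
    tail after the peak, or if the peak sits too close to the start for the
    waveform to begin at rest.
    """
    min_duration = shape.t_peak + 5 * shape.fwhm
    if duration is None:
        duration = min_duration
    if duration < min_duration - 1e-12:
        raise ValueError(
            f"duration {duration:g} s too short: need at least t_peak + 5*fwhm "
            f"= {min_duration:g} s")
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    v = shape.v_rest + _pulse_values(t, shape.amplitude, shape.fwhm,
                                     shape.t_peak, shape.asymmetry)
    for idx, where in ((0, "start"), (-1, "end")):
        if abs(v[idx] - shape.v_rest) > 0.1e-3:
            raise ValueError(
                f"waveform does not return to rest at the {where} "
                f"(off by {abs(v[idx] - shape.v_rest) * 1e3:.3f} mV); "
                f"increase t_peak or duration")
    return TimeSeries(v, dt=dt, t0=0.0, unit="V")


def make_ap_train(shape: APShape, protocol: TrainProtocol,
                  dt: float = SIM_DT) -> TimeSeries:
    """A train of surrogate APs (V).

    The k-th pulse (k = 0, 1, ...) has amplitude ``amplitude * decay^k`` and
    FWHM ``fwhm * broadening^k``; pulses sit at ``t_peak + k * interval``.
    Raises if successive pulses would overlap (interval shorter than five
    times the widest FWHM involved).
    """
    fwhms = shape.fwhm * protocol.broadening ** np.arange(protocol.n_stimuli)
    if protocol.n_stimuli > 1 and protocol.interval < 5 * fwhms.max():
        raise ValueError(
            f"pulses overlap: interval {protocol.interval:g} s < 5 * widest "
            f"FWHM {fwhms.max():g} s")
    duration = (shape.t_peak + (protocol.n_stimuli - 1) * protocol.interval
                + 5 * fwhms[-1] + 5 * shape.fwhm)
    if protocol.n_stimuli > 1:
        # cover a whole number of stimulus epochs so P/5 segmentation fits
        duration = max(duration, protocol.n_stimuli * protocol.interval)
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    v = np.full(n, shape.v_rest)
    for k in range(protocol.n_stimuli):
        amp = shape.amplitude * protocol.amplitude_decay ** k
        v += _pulse_values(t, amp, fwhms[k], shape.t_peak + k * protocol.interval,
                           shape.asymmetry)
    return TimeSeries(v, dt=dt, t0=0.0, unit="V")


def make_calcium_current(amplitude: float, t_peak: float, tau_ca: float,
                         dt: float = SIM_DT, duration: float | None = None) -> TimeSeries:
    """Gaussian presynaptic calcium current (A, inward = negative).

    i(t) = amplitude * exp(-(t - t_peak)^2 / (2 * tau_ca^2)); the FWHM is
    2*sqrt(2*ln 2)*tau_ca.
    """
    if amplitude > 0:
        raise ValueError("calcium current is inward: amplitude must be <= 0")
    if not tau_ca > 0:
        raise ValueError("tau_ca must be > 0")
    if tau_ca < 3 * dt:
        raise ValueError(f"tau_ca {tau_ca:g} s unresolvable at dt {dt:g} s "
                         "(need tau_ca >= 3*dt)")
    if duration is None:
        duration = t_peak + 6 * tau_ca
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    i = amplitude * np.exp(-((t - t_peak) ** 2) / (2 * tau_ca**2))
    return TimeSeries(i, dt=dt, t0=0.0, unit="A")


def make_calcium_train(amplitude: float, tau_ca: float, shape: APShape,
                       protocol: TrainProtocol, dt: float = SIM_DT,
                       peak_offset: float | None = None) -> TimeSeries:
    """Gaussian calcium currents aligned to each AP of a train (A).

    The current peaks during AP repolarization, ``peak_offset`` after each AP
    peak (default: one AP FWHM).
    """
    if peak_offset is None:
        peak_offset = shape.fwhm
    base = make_ap_train(shape, protocol, dt)
    t = base.times
    i = np.zeros_like(t)
    for k in range(protocol.n_stimuli):
        t_pk = shape.t_peak + k * protocol.interval + peak_offset
        i += amplitude * np.exp(-((t - t_pk) ** 2) / (2 * tau_ca**2))
    return TimeSeries(i, dt=dt, t0=0.0, unit="A")


# ---------------------------------------------------------------------------
# paired-recording synthesis
# ---------------------------------------------------------------------------

@dataclass
class RecordingSet:
    """One synthetic paired experiment with its generating ground truth."""

    v_pre: TimeSeries
    i_ca_true: TimeSeries
    active_sweeps: list[TimeSeries]
    passive_sweeps: list[TimeSeries]
    truth: CircuitParams
    seed: int
    scenario: str = "resistive"
    train: TrainProtocol | None = None


def _epsc_waveform(t: np.ndarray, onset: float, epsc: EPSCDescriptor) -> np.ndarray:
    dtp = t - onset
    w = np.where(
        dtp > 0,
        np.exp(-np.maximum(dtp, 0) / epsc.tau_decay)
        - np.exp(-np.maximum(dtp, 0) / epsc.tau_rise),
        0.0,
    )
    m = w.max()
    return epsc.amplitude * w / m if m > 0 else np.zeros_like(t)


def synthesize_paired_recording(
    v_pre: TimeSeries,
    i_ca: TimeSeries,
    params: CircuitParams,
    scenario: str = "resistive",
    noise_sd: float = 0.0,
    n_passive: int = 5,
    epsc: EPSCDescriptor | None = None,
    seed: int = 0,
    specs=None,
) -> RecordingSet:
    """Forward-model a paired voltage-clamp experiment.

    The active sweep is the prespike of ``v_pre`` plus the calcium current
    under the chosen dissipation scenario (``resistive``, ``capacitive`` or
    ``full_ode``); each of the ``n_passive`` passive sweeps uses ``v_pre``
    scaled by exactly 1/5 about rest and elicits no calcium current.
    Gaussian noise of standard deviation ``noise_sd`` (A) is added
    independently to every sweep; an optional EPSC contaminant is added to
    the active sweep only.  A fixed seed gives bit-identical output.
    """
    require_aligned(v_pre, i_ca)
    rng = np.random.default_rng(seed)
    rest = v_pre.values[0]

    def forward(v: TimeSeries, ica: TimeSeries | None) -> np.ndarray:
        if scenario in ("resistive", "capacitive"):
            i = predict_vc_prespike(v, params, scenario).values
            if ica is not None:
                i = i + predict_calcium_prespike(ica, params, scenario).values
            return i
        if scenario == "full_ode":
            sim = simulate_synapse(v, specs or [], params, i_injected=ica)
            return sim.i_rec.values
        raise ValueError(f"unknown scenario {scenario!r}")

    active = forward(v_pre, i_ca)
    if epsc is not None:
        pk, _ = find_peaks(-i_ca.values, height=0.5 * float(np.abs(i_ca.values).max()))
        t = v_pre.times
        for idx in pk:
            active = active + _epsc_waveform(t, t[idx] + epsc.delay, epsc)
    active = active + rng.normal(0.0, noise_sd, active.size)

    v_scaled = v_pre.with_values(rest + (v_pre.values - rest) / 5.0)
    passive_clean = forward(v_scaled, None)
    passive = [
        v_pre.with_values(passive_clean + rng.normal(0.0, noise_sd, passive_clean.size),
                          unit="A")
        for _ in range(n_passive)
    ]
    return RecordingSet(
        v_pre=v_pre,
        i_ca_true=i_ca,
        active_sweeps=[v_pre.with_values(active, unit="A")],
        passive_sweeps=passive,
        truth=params,
        seed=seed,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# on-disk layout: tabular text per signal + JSON metadata
# ---------------------------------------------------------------------------

def write_recording_set(rs: RecordingSet, directory: str | Path) -> None:
    """Write a RecordingSet as a directory of TSV files plus metadata.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tsio.write_timeseries(rs.v_pre, d / "v_pre.tsv", name="v_pre")
    tsio.write_timeseries(rs.i_ca_true, d / "i_ca_true.tsv", name="i_ca")
    for k, s in enumerate(rs.active_sweeps):
        tsio.write_timeseries(s, d / f"active_{k:02d}.tsv", name="i_post")
    for k, s in enumerate(rs.passive_sweeps):
        tsio.write_timeseries(s, d / f"passive_{k:02d}.tsv", name="i_post")
    meta = {
        "seed": rs.seed,
        "scenario": rs.scenario,
        "dt_s": rs.v_pre.dt,
        "t0_s": rs.v_pre.t0,
        "n_active": len(rs.active_sweeps),
        "n_passive": len(rs.passive_sweeps),
        "units": {"v_pre": "mV", "i_ca": "nA", "i_post": "nA"},
        "truth": {
            "c_pre_pF": rs.truth.c_pre / 1e-12,
            "c_syn_pF": rs.truth.c_syn / 1e-12,
            "c_post_pF": rs.truth.c_post / 1e-12,
            "g_cl_uS": rs.truth.g_cl / 1e-6,
            "g_post_nS": rs.truth.g_post / 1e-9,
            "v_rest_mV": rs.truth.v_rest / 1e-3,
            "tau_cl_us": rs.truth.tau_cl / 1e-6,
        },
        "train": None if rs.train is None else asdict(rs.train),
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_recording_set(directory: str | Path) -> RecordingSet:
    """Read a directory written by :func:`write_recording_set`."""
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    tr = meta["truth"]
    truth = CircuitParams(
        c_pre=tr["c_pre_pF"] * 1e-12, c_syn=tr["c_syn_pF"] * 1e-12,
        c_post=tr["c_post_pF"] * 1e-12, g_cl=tr["g_cl_uS"] * 1e-6,
        g_post=tr["g_post_nS"] * 1e-9, v_rest=tr["v_rest_mV"] * 1e-3,
    )
    train = None if meta.get("train") is None else TrainProtocol(**meta["train"])
    return RecordingSet(
        v_pre=tsio.read_timeseries(d / "v_pre.tsv"),
        i_ca_true=tsio.read_timeseries(d / "i_ca_true.tsv"),
        active_sweeps=[tsio.read_timeseries(p)
                       for p in sorted(d.glob("active_*.tsv"))],
        passive_sweeps=[tsio.read_timeseries(p)
                        for p in sorted(d.glob("passive_*.tsv"))],
        truth=truth,
        seed=int(meta["seed"]),
        scenario=meta.get("scenario", "resistive"),
        train=train,
    )
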
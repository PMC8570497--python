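"""Markov-state models of the presynaptic voltage-gated conductances.

Four channel kinds are built in, each a linear chain of states with
voltage-dependent transition rates of the form ``k = a * exp(b * v)`` where
``v`` is the potential the channel senses (for cleft-facing channels,
``v_pre - v_cl``), ``a`` is in 1/ms and ``b`` in 1/mV:

* ``na5``   — sodium, five states C1=C2=C3=O=I with 2a/b, a/2b stoichiometry
              on the closed chain, activation g/d, and inactivation O->I (rate
              theta) with recovery I->O (rate epsilon);
* ``k6_ht`` — high-threshold potassium, six states C1..C5=O with 4a/b .. a/4b
              stoichiometry and voltage-independent g/d;
* ``k6_lt`` — low-threshold potassium, same topology, different constants;
* ``ca2``   — calcium, two states C=O whose open probability is squared
              (two independent gates).

This module works in the units the rate constants are tabulated in (mV, 1/ms);
the circuit integrator converts at its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "Transition",
    "ChannelSpec",
    "StateVector",
    "transition_rate",
    "rate_matrix",
    "occupancy_derivative",
    "open_probability",
    "steady_state_occupancy",
    "builtin_channel",
    "channel_from_config",
    "BUILTIN_RATES",
]

#: exponent clamp: beyond +-50 the exponential is held constant for safety
_EXP_CLAMP = 50.0


def transition_rate(a: float, b: float, v: float | np.ndarray) -> float | np.ndarray:
    """Rate ``a * exp(b * v)`` in 1/ms for a in 1/ms, b in 1/mV, v in mV.

    ``b = 0`` gives a voltage-independent rate.  The exponent argument is
    clamped to +-50, far outside the physiological range.
    """
    return a * np.exp(np.clip(b * np.asarray(v, dtype=float), -_EXP_CLAMP, _EXP_CLAMP))


@dataclass(frozen=True)
class Transition:
    """One directed transition ``source -> target`` with rate ``a*exp(b*v)``.

    Stoichiometric multipliers of the chain schemes (2a, 3b, ...) are folded
    into ``a``.
    """

    source: int
    target: int
    a: float  # 1/ms
    b: float  # 1/mV

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("rate prefactor a must be >= 0")


# Rate constants (a in 1/ms, b in 1/mV) for the built-in channel kinds.
BUILTIN_RATES: dict[str, dict[str, tuple[float, float]]] = {
    "na5": {
        "alpha": (48.9, 1 / 128.4),
        "beta": (1.46, -1 / 8.9),
        "gamma": (392.8, 1 / 36.0),
        "delta": (0.73, -1 / 15.5),
        "epsilon": (7.8, 1 / 35.9),
        "theta": (0.01, -1 / 18.0),
    },
    "k6_ht": {
        "alpha": (1.097, 1 / 57.404),
        "beta": (0.794, -1 / 79.264),
        "gamma": (33.750, 0.0),
        "delta": (74.360, 0.0),
    },
    "k6_lt": {
        "alpha": (1.204, 1 / 37.574),
        "beta": (0.360, -1 / 230.0),
        "gamma": (245.488, 0.0),
        "delta": (132.566, 0.0),
    },
    "ca2": {
        "alpha": (1.78, 1 / 23.3),
        "beta": (0.14, -1 / 15.0),
    },
}

#: default reversal potential per kind, mV
DEFAULT_REVERSAL = {"na5": 50.0, "k6_ht": -90.0, "k6_lt": -90.0, "ca2": 40.0}

#: default conductance density per kind, nS/um^2 (homogeneous-model values)
DEFAULT_DENSITY = {"na5": 0.2, "k6_ht": 0.08, "k6_lt": 0.24, "ca2": 0.04}

_STATE_NAMES = {
    "na5": ("C1", "C2", "C3", "O", "I"),
    "k6_ht": ("C1", "C2", "C3", "C4", "C5", "O"),
    "k6_lt": ("C1", "C2", "C3", "C4", "C5", "O"),
    "ca2": ("C", "O"),
}


def _chain_transitions(kind: str, rates: dict[str, tuple[float, float]]) -> tuple[Transition, ...]:
    a, b = rates["alpha"], rates["beta"]
    if kind == "na5":
        g, d = rates["gamma"], rates["delta"]
        e, th = rates["epsilon"], rates["theta"]
        return (
            Transition(0, 1, 2 * a[0], a[1]), Transition(1, 0, b[0], b[1]),
            Transition(1, 2, a[0], a[1]), Transition(2, 1, 2 * b[0], b[1]),
            Transition(2, 3, g[0], g[1]), Transition(3, 2, d[0], d[1]),
            Transition(3, 4, th[0], th[1]), Transition(4, 3, e[0], e[1]),
        )
    if kind in ("k6_ht", "k6_lt"):
        g, d = rates["gamma"], rates["delta"]
        out: list[Transition] = []
        for i in range(4):
            out.append(Transition(i, i + 1, (4 - i) * a[0], a[1]))
            out.append(Transition(i + 1, i, (i + 1) * b[0], b[1]))
        out.append(Transition(4, 5, g[0], g[1]))
        out.append(Transition(5, 4, d[0], d[1]))
        return tuple(out)
    if kind == "ca2":
        return (Transition(0, 1, a[0], a[1]), Transition(1, 0, b[0], b[1]))
    raise ValueError(f"unknown channel kind {kind!r}")


@dataclass(frozen=True)
class ChannelSpec:
    """A Markov channel scheme plus its macroscopic conductance parameters."""

    kind: str
    transitions: tuple[Transition, ...]
    state_names: tuple[str, ...]
    open_state: int
    g_max_density: float  # nS/um^2
    area: float  # um^2
    v_reversal: float  # mV
    squared: bool = False  # open probability squared (two independent gates)

    def __post_init__(self) -> None:
        n = len(self.state_names)
        for tr in self.transitions:
            if not (0 <= tr.source < n and 0 <= tr.target < n):
                raise ValueError(f"transition {tr} outside the {n}-state scheme")
        if not 0 <= self.open_state < n:
            raise ValueError("open_state index out of range")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def g_max(self) -> float:
        """Maximal conductance in nS."""
        return self.g_max_density * self.area

    def with_density(self, g_max_density: float) -> "ChannelSpec":
        return replace(self, g_max_density=g_max_density)


@dataclass
class StateVector:
    """State occupancies: probabilities summing to one."""

    occupancies: np.ndarray

    def __post_init__(self) -> None:
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        p = self.occupancies
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"occupancies must sum to 1, got {p.sum()}")


def builtin_channel(kind: str, *, density: float | None = None,
                    area: float = 1000.0, v_reversal: float | None = None) -> ChannelSpec:
    """Construct one of the built-in channel kinds with its tabulated rates.

    Parameters
    ----------
    kind
        ``"na5"``, ``"k6_ht"``, ``"k6_lt"`` or ``"ca2"``.
    density
        Conductance density in nS/um^2 (default: the homogeneous-model value).
    area
        Cleft-facing membrane area in um^2.
    v_reversal
        Reversal potential in mV (default per kind).
    """
    if kind not in BUILTIN_RATES:
        raise ValueError(f"unknown channel kind {kind!r}; options: {sorted(BUILTIN_RATES)}")
    names = _STATE_NAMES[kind]
    return ChannelSpec(
        kind=kind,
        transitions=_chain_transitions(kind, BUILTIN_RATES[kind]),
        state_names=names,
        open_state=names.index("O"),
        g_max_density=DEFAULT_DENSITY[kind] if density is None else density,
        area=area,
        v_reversal=DEFAULT_REVERSAL[kind] if v_reversal is None else v_reversal,
        squared=(kind == "ca2"),
    )


def channel_from_config(cfg: dict) -> ChannelSpec:
    """Build a ChannelSpec from a config mapping.

    Keys: ``kind`` (required), ``density`` (nS/um^2), ``area`` (um^2),
    ``reversal`` (mV) and optionally ``rates``: a mapping of rate names to
    ``[a, b]`` pairs overriding the built-in constants for that kind.
    """
    kind = cfg["kind"]
    rates = dict(BUILTIN_RATES[kind])
    for name, ab in cfg.get("rates", {}).items():
        if name not in rates:
            raise ValueError(f"rate {name!r} is not part of the {kind!r} scheme")
        rates[name] = (float(ab[0]), float(ab[1]))
    names = _STATE_NAMES[kind]
    return ChannelSpec(
        kind=kind,
        transitions=_chain_transitions(kind, rates),
        state_names=names,
        open_state=names.index("O"),
        g_max_density=float(cfg.get("density", DEFAULT_DENSITY[kind])),
        area=float(cfg.get("area", 1000.0)),
        v_reversal=float(cfg.get("reversal", DEFAULT_REVERSAL[kind])),
        squared=(kind == "ca2"),
    )


def rate_matrix(spec: ChannelSpec, v: float) -> np.ndarray:
    """Generator matrix Q (1/ms) at potential v (mV): dp/dt = p @ Q.

    Off-diagonal ``Q[i, j]`` is the rate i -> j; rows sum to zero.
    """
    n = spec.n_states
    q = np.zeros((n, n))
    for tr in spec.transitions:
        k = transition_rate(tr.a, tr.b, v)
        q[tr.source, tr.target] += k
        q[tr.source, tr.source] -= k
    return q


def occupancy_derivative(spec: ChannelSpec, state: StateVector | np.ndarray, v: float) -> np.ndarray:
    """Master-equation derivative dp/dt (1/ms); components sum to zero."""
    p = state.occupancies if isinstance(state, StateVector) else np.asarray(state, float)
    if p.size != spec.n_states:
        raise ValueError(f"state has {p.size} entries, scheme has {spec.n_states} states")
    return p @ rate_matrix(spec, v)


def open_probability(spec: ChannelSpec, state: StateVector | np.ndarray) -> float:
    """Open probability: O-occupancy, squared for the two-gate calcium scheme."""
    p = state.occupancies if isinstance(state, StateVector) else np.asarray(state, float)
    po = float(p[spec.open_state])
    return po * po if spec.squared else po


def steady_state_occupancy(spec: ChannelSpec, v: float) -> StateVector:
    """Stationary occupancy at fixed potential v (mV).

    The null space of the generator, normalized to sum one.  Raises if the
    generator is reducible at v (null space dimension != 1).
    """
    q = rate_matrix(spec, v)
    ns = scipy.linalg.null_space(q.T, rcond=1e-12)
    if ns.shape[1] != 1:
        raise ValueError(
            f"degenerate generator for {spec.kind} at v={v} mV: "
            f"null space dimension {ns.shape[1]}"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-9):
        raise ValueError(f"non-physical stationary vector for {spec.kind} at v={v} mV")
    return StateVector(np.clip(p, 0.0, 1.0) / np.clip(p, 0.0, 1.0).sum())
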
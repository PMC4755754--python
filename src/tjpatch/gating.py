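"""Continuous-time Markov models of paracellular channel gating.

The claudin-2 channel is modelled with one open state and two closed
states arranged linearly, ``c_stable ↔ o ↔ c_transient``, so that a
recording shows bursts: rapid o/c_transient flicker terminated when the
channel enters the long-lived c_stable state.  Transition rates are
collected in a generator (Q) matrix in s⁻¹; each state's sojourn time is
exponential with mean equal to the reciprocal of its total exit rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GatingModel",
    "StatePath",
    "claudin2_model",
    "independent_channel_model",
    "off_junction_model",
    "two_state_model",
    "simulate_state_path",
    "stationary_distribution",
    "concat_paths",
]

OPEN = "open"
CLOSED = "closed"


class InvalidModelError(ValueError):
    """Raised when a rate table is not a valid CTMC generator."""


@dataclass(frozen=True)
class GatingModel:
    """A labelled-state gating scheme with per-state conductance.

    Parameters
    ----------
    state_labels
        Names of the kinetic states, e.g. ``("c_stable", "o", "c_transient")``.
    state_class
        ``"open"`` or ``"closed"`` per state.
    rates
        Square generator matrix in s⁻¹: off-diagonal entries are
        transition rates, diagonal entries the negative row sums.
    pore_conductance
        Conductance in pS per state; must be 0 for closed states.
    reversal_potential
        Channel reversal potential in mV.
    """

    state_labels: tuple[str, ...]
    state_class: tuple[str, ...]
    rates: np.ndarray
    pore_conductance: tuple[float, ...]
    reversal_potential: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", q)
        n = len(self.state_labels)
        if q.shape != (n, n):
            raise InvalidModelError("rate table must be square, one row per state")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            raise InvalidModelError("off-diagonal rates must be >= 0")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-9 * max(1.0, np.abs(q).max())):
            raise InvalidModelError("generator rows must sum to 0")
        if len(self.state_class) != n or len(self.pore_conductance) != n:
            raise InvalidModelError("state_class and pore_conductance must match states")
        if OPEN not in self.state_class or CLOSED not in self.state_class:
            raise InvalidModelError("need at least one open and one closed state")
        for cls, g in zip(self.state_class, self.pore_conductance):
            if g < 0:
                raise InvalidModelError("conductances must be >= 0")
            if cls == CLOSED and g != 0:
                raise InvalidModelError("closed states must have zero conductance")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def open_states(self) -> np.ndarray:
        return np.array([c == OPEN for c in self.state_class])

    def scaled(self, factor: float) -> "GatingModel":
        """Return a copy with all rates multiplied by ``factor``.

        Scaling the whole generator changes how fast the channel moves
        between states but not the stationary occupancy.
        """
        return GatingModel(
            self.state_labels,
            self.state_class,
            self.rates * factor,
            self.pore_conductance,
            self.reversal_potential,
        )


@dataclass
class StatePath:
    """Piecewise-constant state trajectory of one channel.

    ``times[i]`` is the entry time of ``states[i]``; the first entry is 0
    and the trajectory extends to ``duration``.
    """

    times: np.ndarray
    states: np.ndarray
    duration: float
    model: GatingModel = field(repr=False)

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State index at each query time (vectorized)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def conductance_at(self, t: np.ndarray) -> np.ndarray:
        g = np.asarray(self.model.pore_conductance, dtype=float)
        return g[self.state_at(t)]

    def open_sojourns(self) -> list[tuple[float, float]]:
        """(start, duration) of every visit to an open state."""
        is_open = self.model.open_states[self.states]
        ends = np.append(self.times[1:], self.duration)
        return [
            (float(t0), float(t1 - t0))
            for t0, t1, o in zip(self.times, ends, is_open)
            if o and t1 > t0
        ]

    def truncated(self, t_stop: float, closed_state: int | None = None) -> "StatePath":
        """Force the channel into a closed state from ``t_stop`` onward.

        Used for pharmacological block: the channel gates normally until
        ``t_stop`` and is then pinned closed for the rest of the record.
        """
        if t_stop >= self.duration:
            return self
        if closed_state is None:
            closed_state = next(
                i for i, c in enumerate(self.model.state_class) if c == CLOSED
            )
        keep = self.times < t_stop
        times = np.append(self.times[keep], t_stop)
        states = np.append(self.states[keep], closed_state)
        return StatePath(times, states, self.duration, self.model)


def simulate_state_path(
    model: GatingModel,
    duration: float,
    seed: int | np.random.Generator,
    start_state: int | None = None,
) -> StatePath:
    """Simulate one channel's gating trajectory by the Gillespie algorithm.

    Each sojourn in state *i* is exponential with mean ``-1/Q[i, i]``;
    the successor is drawn with probabilities proportional to the
    off-diagonal rates of row *i*.  Reproducible given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = model.rates
    n = model.n_states
    exit_rates = -np.diag(q)
    jump = np.zeros((n, n))
    for i in range(n):
        if exit_rates[i] > 0:
            jump[i] = q[i] / exit_rates[i]
            jump[i, i] = 0.0
    if start_state is None:
        pi = stationary_distribution(model)
        state = int(rng.choice(n, p=pi))
    else:
        state = int(start_state)

    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        k = exit_rates[state]
        if k <= 0:  # absorbing state: sojourn spans the rest of the record
            break
        t += rng.exponential(1.0 / k)
        if t >= duration:
            break
        state = int(rng.choice(n, p=jump[state]))
        times.append(t)
        states.append(state)
    return StatePath(np.asarray(times), np.asarray(states, dtype=np.intp), duration, model)


def stationary_distribution(model: GatingModel) -> np.ndarray:
    """Stationary occupancy of the gating scheme.

    Solves πQ = 0, Σπ = 1 via the null space of Qᵀ.
    """
    q = model.rates
    n = model.n_states
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def concat_paths(first: StatePath, second: StatePath) -> StatePath:
    """Concatenate two trajectories in time (second shifted after first).

    The two paths must share state labelling; the result carries the
    second path's model (used e.g. when rates change mid-record).
    """
    if first.model.state_labels != second.model.state_labels:
        raise ValueError("paths must share state labels")
    times = np.concatenate([first.times, second.times + first.duration])
    states = np.concatenate([first.states, second.states])
    return StatePath(times, states, first.duration + second.duration, second.model)


def two_state_model(
    tau_open_s: float,
    tau_closed_s: float,
    conductance_ps: float,
    reversal_potential: float = 0.0,
) -> GatingModel:
    """Minimal closed ↔ open scheme from mean dwell times."""
    ko, kc = 1.0 / tau_open_s, 1.0 / tau_closed_s
    q = np.array([[-kc, kc], [ko, -ko]])
    return GatingModel(("c", "o"), (CLOSED, OPEN), q, (0.0, conductance_ps), reversal_potential)


def claudin2_model(
    conductance_ps: float = 90.0,
    tau_open_s: float = 0.6e-3,
    tau_closed_transient_s: float = 1.2e-3,
    tau_closed_stable_s: float = 3.0,
    p_terminate: float = 0.1,
    reversal_potential: float = 0.0,
) -> GatingModel:
    """Default claudin-2 gating scheme ``c_stable ↔ o ↔ c_transient``.

    ``p_terminate`` is the probability that a closure ends the burst
    (o → c_stable) rather than flickering (o → c_transient); with the
    default 0.1, bursts contain a geometric mean of 10 openings and
    closed dwells are a 0.9/0.1 mixture of the transient and stable
    components.
    """
    k_open_exit = 1.0 / tau_open_s
    k_cs = 1.0 / tau_closed_stable_s
    k_ct = 1.0 / tau_closed_transient_s
    o_to_cs = p_terminate * k_open_exit
    o_to_ct = (1.0 - p_terminate) * k_open_exit
    q = np.array(
        [
            [-k_cs, k_cs, 0.0],
            [o_to_cs, -k_open_exit, o_to_ct],
            [0.0, k_ct, -k_ct],
        ]
    )
    return GatingModel(
        ("c_stable", "o", "c_transient"),
        (CLOSED, OPEN, CLOSED),
        q,
        (0.0, conductance_ps, 0.0),
        reversal_potential,
    )


def independent_channel_model(conductance_ps: float = 43.0) -> GatingModel:
    """The claudin-2-independent ~4.3 pA (at 100 mV) event class.

    Present regardless of claudin-2 expression and cold-resistant;
    modelled as a simple two-state channel with longer openings than the
    claudin-2 flicker.
    """
    return two_state_model(1.5e-3, 0.4, conductance_ps)


def off_junction_model(conductance_ps: float = 15.0, tau_closed_s: float = 2.0) -> GatingModel:
    """Sub-2 pA apical-membrane channel seen off the tight junction.

    Openings are long (8 ms) but small, so they are only resolvable
    after additional 500 Hz low-pass filtering.  More active at +100 mV
    than −100 mV; callers model that by passing a smaller
    ``tau_closed_s`` for the depolarized segment.
    """
    return two_state_model(8e-3, tau_closed_s, conductance_ps)
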
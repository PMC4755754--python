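"""Voltage-ramp analysis: baseline subtraction, event I-V, V_rev.

Repetitive 1 s ramps from −100 to +100 mV are classified into
event-free and event-containing sweeps; the mean event-free sweep is
subtracted pointwise (removing the seal leak and any slow capacitive
component), and the remaining open-channel samples are pooled into an
I-V cloud fitted with a straight line.  The zero crossing gives the
reversal potential and the slope the single-channel conductance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import CurrentTrace

__all__ = [
    "RampSet",
    "IVResult",
    "block_average",
    "classify_sweeps",
    "subtract_baseline_ramps",
    "fit_iv",
    "event_conductance",
]


@dataclass
class RampSet:
    """Sweeps sharing one ramp protocol, with per-sweep opening flags."""

    sweeps: list[CurrentTrace]
    open_flags: list[bool] | None = None

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("need at least one sweep")
        proto = self.sweeps[0].protocol
        for s in self.sweeps[1:]:
            if s.protocol != proto or s.n_samples != self.sweeps[0].n_samples:
                raise ValueError("all sweeps must share protocol and length")


@dataclass
class IVResult:
    v_rev: float  # mV
    slope_conductance: float  # pS
    fit_residual: float  # pA RMS

    def __post_init__(self) -> None:
        if self.slope_conductance < 0:
            raise ValueError("slope conductance must be >= 0")


def block_average(trace: CurrentTrace, factor: int) -> CurrentTrace:
    """Decimate by averaging blocks of ``factor`` consecutive samples.

    The digital analogue of oversampling at 100 kHz and averaging down
    to 10 kHz: reduces noise without distorting the slow ramp response.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = (trace.n_samples // factor) * factor
    x = trace.samples[:n].reshape(-1, factor).mean(axis=1)
    return CurrentTrace(
        x,
        trace.sampling_rate / factor,
        trace.protocol,
        dict(trace.metadata, block_averaged=factor),
    )


def _unitary_amplitude(v: np.ndarray, gamma_ps: float, v_rev: float = 0.0) -> np.ndarray:
    return gamma_ps * (v - v_rev) / 1000.0


def classify_sweeps(
    ramp_set: RampSet,
    gamma_ps: float = 90.0,
    min_duration: float = 0.2e-3,
    min_amplitude_pa: float = 2.0,
) -> RampSet:
    """Flag sweeps that contain openings, using a voltage-scaled threshold.

    The pointwise median across sweeps estimates the event-free response
    (openings are sparse).  A sweep is event-containing if its residual
    crosses half the expected unitary amplitude — where that amplitude
    exceeds ``min_amplitude_pa`` — for at least ``min_duration``.
    """
    stack = np.stack([s.samples for s in ramp_set.sweeps])
    baseline = np.median(stack, axis=0)
    v = ramp_set.sweeps[0].voltages()
    unitary = _unitary_amplitude(v, gamma_ps)
    detectable = np.abs(unitary) >= min_amplitude_pa
    fs = ramp_set.sweeps[0].sampling_rate
    min_samples = max(1, int(round(min_duration * fs)))
    flags = []
    for s in ramp_set.sweeps:
        resid = s.samples - baseline
        above = detectable & (np.abs(resid) >= np.abs(unitary) / 2) & (np.sign(resid) == np.sign(unitary))
        # longest run of consecutive above-threshold samples
        run, longest = 0, 0
        for a in above:
            run = run + 1 if a else 0
            longest = max(longest, run)
        flags.append(longest >= min_samples)
    return RampSet(ramp_set.sweeps, flags)


def subtract_baseline_ramps(
    ramp_set: RampSet,
    gamma_ps: float = 90.0,
    min_amplitude_pa: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-only I-V samples after event-free sweep subtraction.

    The mean of the event-free sweeps is subtracted pointwise from each
    event-containing sweep; samples beyond the half-amplitude criterion
    are pooled and returned as (voltage mV, current pA) arrays.
    """
    rs = ramp_set if ramp_set.open_flags is not None else classify_sweeps(
        ramp_set, gamma_ps, min_amplitude_pa=min_amplitude_pa
    )
    flags = np.asarray(rs.open_flags, dtype=bool)
    if not flags.any():
        raise ValueError("no event-containing sweep")
    if flags.all():
        raise ValueError("no event-free sweep available for subtraction")
    stack = np.stack([s.samples for s in rs.sweeps])
    baseline = stack[~flags].mean(axis=0)
    v = rs.sweeps[0].voltages()
    unitary = _unitary_amplitude(v, gamma_ps)
    detectable = np.abs(unitary) >= min_amplitude_pa
    vs, cs = [], []
    for s in stack[flags]:
        resid = s - baseline
        mask = detectable & (np.abs(resid) >= np.abs(unitary) / 2) & (
            np.sign(resid) == np.sign(unitary)
        )
        vs.append(v[mask])
        cs.append(resid[mask])
    return np.concatenate(vs), np.concatenate(cs)


def fit_iv(v_mv: np.ndarray, i_pa: np.ndarray) -> IVResult:
    """Least-squares line through (V, I) points; V_rev is the zero crossing."""
    v = np.asarray(v_mv, dtype=float)
    i = np.asarray(i_pa, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need at least 2 voltage-distinct points")
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise ValueError("degenerate (flat) I-V relation")
    resid = i - (slope * v + intercept)
    return IVResult(
        v_rev=float(-intercept / slope),
        slope_conductance=float(abs(slope) * 1000.0),  # pA/mV -> pS
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )


def event_conductance(amplitude_pa: float, v_mv: float, v_rev_mv: float = 0.0) -> float:
    """Chord conductance in pS of an event of ``amplitude_pa`` at ``v_mv``."""
    if v_mv == v_rev_mv:
        raise ValueError("driving force is zero at the reversal potential")
    return abs(1000.0 * amplitude_pa / (v_mv - v_rev_mv))
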
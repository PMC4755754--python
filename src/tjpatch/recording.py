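"""Render gating trajectories into patch-clamp current traces.

The instantaneous patch current is the sum over open channels of
γ·(V − V_rev)/1000 (pA), plus the pipette seal-leak current V/R_seal,
plus Gaussian noise.  The sum is low-pass filtered with a 4-pole Bessel
filter (the digital stand-in for the amplifier's analog filter) and
decimated to the recording sampling rate.

Sign convention: negative currents correspond to cations moving toward
the recording electrode, so an open 90 pS channel at a −100 mV holding
potential produces a −9 pA deflection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .gating import GatingModel, StatePath
from .protocol import VoltageProtocol

__all__ = ["RecordingConfig", "CurrentTrace", "render_current", "lowpass", "bessel_sos"]


@dataclass(frozen=True)
class RecordingConfig:
    """Acquisition settings for a simulated recording.

    ``noise_sd`` is the RMS baseline noise of the *filtered* trace in pA;
    the white noise injected before filtering is scaled so the output
    noise matches it regardless of the filter cutoff.
    ``temperature_scale`` is a phenomenological cooling knob: it
    multiplies all gating rates and the active-channel count.
    """

    sampling_rate: float = 25_000.0
    filter_cutoff: float = 5_000.0
    noise_sd: float = 0.6
    seal_resistance: float = 30.0  # GΩ; np.inf disables the leak
    n_channels: int = 1
    duration: float = 20.0
    rng_seed: int = 0
    temperature_scale: float = 1.0
    oversample: int = 2  # internal rendering rate = oversample × sampling_rate

    def __post_init__(self) -> None:
        if self.sampling_rate < 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must be >= 2 x filter_cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_channels < 0:
            raise ValueError("n_channels must be >= 0")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")


@dataclass
class CurrentTrace:
    """Sampled current (pA) with its voltage protocol and provenance."""

    samples: np.ndarray
    sampling_rate: float
    protocol: VoltageProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def voltages(self) -> np.ndarray:
        return self.protocol.voltage_at(self.times())

    def slice(self, t0: float, t1: float) -> "CurrentTrace":
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        out = replace(self, samples=self.samples[i0:i1].copy())
        out.metadata = dict(self.metadata, slice=(t0, t1))
        return out


def bessel_sos(cutoff_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """4-pole low-pass Bessel filter, −3 dB at ``cutoff_hz``."""
    return signal.bessel(order, cutoff_hz, fs=fs, output="sos", norm="mag")


def _white_noise_gain(sos: np.ndarray, n: int = 8192) -> float:
    """Output RMS of the filter for unit-variance white input."""
    impulse = np.zeros(n)
    impulse[0] = 1.0
    h = signal.sosfilt(sos, impulse)
    return float(np.sqrt(np.sum(h**2)))


def render_current(
    paths: list[StatePath],
    protocol: VoltageProtocol,
    config: RecordingConfig,
    model: GatingModel | list[GatingModel] | None = None,
    metadata: dict | None = None,
) -> CurrentTrace:
    """Render per-channel state trajectories into one filtered trace.

    ``model`` may be a single gating model shared by all channels, a
    list (one per path), or None to use each path's own model.
    """
    duration = protocol.duration_s
    for p in paths:
        if p.duration < duration - 1e-9:
            raise ValueError("trajectories must cover the protocol duration")

    if model is None:
        models = [p.model for p in paths]
    elif isinstance(model, GatingModel):
        models = [model] * len(paths)
    else:
        models = list(model)
        if len(models) != len(paths):
            raise ValueError("one model per path required")

    fs_render = config.sampling_rate * config.oversample
    n_render = int(round(duration * fs_render))
    t = np.arange(n_render) / fs_render
    v = protocol.voltage_at(t)

    current = np.zeros(n_render)
    for path, m in zip(paths, models):
        g = np.asarray(m.pore_conductance, dtype=float)[path.state_at(t)]
        current += g * (v - m.reversal_potential) / 1000.0
    if np.isfinite(config.seal_resistance):
        current += v / config.seal_resistance

    sos = bessel_sos(config.filter_cutoff, fs_render)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed)
        sigma_white = config.noise_sd / _white_noise_gain(sos)
        current = current + rng.normal(0.0, sigma_white, n_render)
    filtered = signal.sosfilt(sos, current)
    samples = filtered[:: config.oversample]

    meta = {"config": config, "scenario": None, "seed": config.rng_seed}
    if metadata:
        meta.update(metadata)
    return CurrentTrace(samples, config.sampling_rate, protocol, meta)


def lowpass(trace: CurrentTrace, cutoff_hz: float, order: int = 4) -> CurrentTrace:
    """Apply an additional digital Bessel low-pass to an existing trace.

    Used for off-junction analysis, where sub-2 pA openings only become
    resolvable after 500 Hz filtering.
    """
    if cutoff_hz >= trace.sampling_rate / 2:
        warnings.warn("cutoff at or above Nyquist; returning trace unchanged")
        return trace
    sos = bessel_sos(cutoff_hz, trace.sampling_rate, order)
    out = CurrentTrace(
        signal.sosfilt(sos, trace.samples),
        trace.sampling_rate,
        trace.protocol,
        dict(trace.metadata, extra_filter_hz=cutoff_hz),
    )
    return out
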
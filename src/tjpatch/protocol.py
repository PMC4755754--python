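"""Voltage-clamp command protocols (holds and linear ramps)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Segment", "VoltageProtocol", "hold", "ramp_protocol"]


@dataclass(frozen=True)
class Segment:
    kind: str  # "hold" | "ramp"
    start_mv: float
    end_mv: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "ramp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be > 0")
        if self.kind == "hold" and self.start_mv != self.end_mv:
            raise ValueError("hold segments must keep a constant voltage")


@dataclass(frozen=True)
class VoltageProtocol:
    """Sequence of hold/ramp segments; ramps interpolate linearly."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def voltage_at(self, t: np.ndarray) -> np.ndarray:
        """Command voltage (mV) at each time in ``t`` (s), vectorized."""
        t = np.asarray(t, dtype=float)
        v = np.empty_like(t)
        t0 = 0.0
        for i, seg in enumerate(self.segments):
            t1 = t0 + seg.duration_s
            if i == len(self.segments) - 1:
                mask = (t >= t0) & (t <= t1 + 1e-12)
            else:
                mask = (t >= t0) & (t < t1)
            frac = (t[mask] - t0) / seg.duration_s
            v[mask] = seg.start_mv + frac * (seg.end_mv - seg.start_mv)
            t0 = t1
        return v

    def to_dict(self) -> list[dict]:
        return [
            {"kind": s.kind, "start_mv": s.start_mv, "end_mv": s.end_mv, "duration_s": s.duration_s}
            for s in self.segments
        ]

    @classmethod
    def from_dict(cls, data: list[dict]) -> "VoltageProtocol":
        return cls(tuple(Segment(d["kind"], d["start_mv"], d["end_mv"], d["duration_s"]) for d in data))


def hold(v_mv: float, duration_s: float) -> VoltageProtocol:
    """Constant holding potential."""
    return VoltageProtocol((Segment("hold", v_mv, v_mv, duration_s),))


def ramp_protocol(
    start_mv: float = -100.0, end_mv: float = 100.0, duration_s: float = 1.0
) -> VoltageProtocol:
    """The standard 1 s −100 → +100 mV voltage ramp."""
    return VoltageProtocol((Segment("ramp", start_mv, end_mv, duration_s),))
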
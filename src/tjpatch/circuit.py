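"""Equivalent-circuit algebra for trans-tight-junction recordings.

Every conductive pathway seen by the patch pipette — electrode, pipette
seal leak, apical-membrane channels, the two paracellular channel
classes, and the monolayer shunt outside the pipette — is an ohmic
resistor.  Unit conventions make the arithmetic direct: mV / pA = GΩ,
and areal resistance (Ω·cm²) divided by support area (cm²) gives Ω.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, log10

import numpy as np

__all__ = [
    "CircuitModel",
    "ter_from_pulses",
    "ohmic_resistance",
    "pathway_current",
    "areal_to_absolute",
    "combine_pathways",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (the reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def ter_from_pulses(dv_mv: float, di_ua: float, area_cm2: float) -> float:
    """Transepithelial resistance (Ω·cm²) from a current-clamp pulse.

    Ohm's law on the voltage deflection: (ΔV/ΔI)·area, with ΔV in mV and
    ΔI in µA (mV/µA = kΩ → 1000 Ω).
    """
    if di_ua == 0:
        raise ValueError("zero current step")
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    return abs(dv_mv / di_ua) * 1000.0 * area_cm2


def ohmic_resistance(current_pa: float, voltage_mv: float) -> float:
    """Pathway resistance in GΩ from an event amplitude (mV/pA = GΩ)."""
    if current_pa == 0:
        raise ValueError("zero current")
    return abs(voltage_mv / current_pa)


def pathway_current(resistance_gohm: float, voltage_mv: float) -> float:
    """Current in pA through a pathway of given resistance (V/R)."""
    if resistance_gohm == 0:
        raise ValueError("zero resistance")
    return voltage_mv / resistance_gohm


def areal_to_absolute(r_areal_ohm_cm2: float, area_cm2: float) -> float:
    """Convert an areal resistance to the absolute resistance in MΩ."""
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    return r_areal_ohm_cm2 / area_cm2 / 1e6


def combine_pathways(
    resistances_gohm: dict[str, float] | list[float],
    mode: str,
    subset: list[str] | None = None,
) -> float:
    """Series or parallel combination of pathway resistances (GΩ)."""
    if isinstance(resistances_gohm, dict):
        names = subset if subset is not None else list(resistances_gohm)
        if not names:
            raise ValueError("empty pathway subset")
        values = np.array([resistances_gohm[n] for n in names], dtype=float)
    else:
        values = np.asarray(resistances_gohm, dtype=float)
        if values.size == 0:
            raise ValueError("empty pathway subset")
    if np.any(values <= 0):
        raise ValueError("resistances must be > 0")
    if mode == "series":
        return float(values.sum())
    if mode == "parallel":
        return float(1.0 / np.sum(1.0 / values))
    raise ValueError("mode must be 'series' or 'parallel'")


@dataclass
class CircuitModel:
    """Named pathway resistances (GΩ) of the recording configuration.

    Defaults follow the measured values: 2.5 MΩ electrode, ~30 GΩ seal
    leak, 50 GΩ apical-membrane pathway, 11 GΩ claudin-2 channel,
    25 GΩ independent channel, and a monolayer shunt so small
    (sub-MΩ) that it is effectively a short relative to the rest.
    """

    resistances: dict[str, float] = field(
        default_factory=lambda: {
            "electrode": 2.5e-3,  # 2.5 MΩ
            "seal_leak": 30.0,
            "apical_membrane_path": 50.0,
            "cldn2_channel": 11.0,
            "independent_channel": 25.0,
            "monolayer_shunt": 4.5e-9,  # 0.0045 MΩ
        }
    )
    support_area_cm2: float = 0.33

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.resistances.values()):
            raise ValueError("all resistances must be > 0")
        if self.support_area_cm2 <= 0:
            raise ValueError("support area must be > 0")

    def series(self, subset: list[str]) -> float:
        return combine_pathways(self.resistances, "series", subset)

    def parallel(self, subset: list[str]) -> float:
        return combine_pathways(self.resistances, "parallel", subset)

    def event_current(self, pathway: str, voltage_mv: float, with_electrode: bool = True) -> float:
        """pA through one pathway in series with the electrode."""
        r = self.resistances[pathway]
        if with_electrode:
            r = r + self.resistances.get("electrode", 0.0)
        return pathway_current(r, voltage_mv)
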
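"""Electrochemical algebra: GHK relative permeabilities and absolute P_Na.

Reversal potentials measured under dilution or biionic conditions are
converted to relative permeabilities with the Goldman–Hodgkin–Katz
voltage equation over monovalent ions,

    V_rev = (RT/F) · ln[(Σ_cat P·a_baso + Σ_an P·a_api) /
                        (Σ_cat P·a_api + Σ_an P·a_baso)],

with the transepithelial convention V = V_apical − V_basal and ion
activities a = γ±·c.  Absolute Na⁺ permeability follows from the
transepithelial conductance and P_Na/P_Cl by the Kimizuka–Koketsu
relation  P_Na = (RT/F²)·G·[r/(1+r)]/a_Na  with r = P_Na/P_Cl, G in
S/cm² and a_Na in mol/cm³, giving cm/s.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import FARADAY, R_GAS, T_BODY, mm_to_mol_per_cm3

__all__ = [
    "Ion",
    "IonicConditions",
    "PermeabilityResult",
    "activity_coefficient_nacl",
    "hbss",
    "biionic_conditions",
    "ghk_vrev",
    "invert_ghk_dilution",
    "biionic_px_over_pna",
    "kimizuka_koketsu_pna",
]

#: Mean NaCl activity coefficients at the three working concentrations.
NACL_ACTIVITY_TABLE = ((13.5, 0.882), (67.5, 0.812), (135.0, 0.755))


def activity_coefficient_nacl(conc_mm: float) -> float:
    """NaCl mean activity coefficient, log-linearly interpolated.

    Anchored at the tabulated values 0.882, 0.812 and 0.755 for 13.5,
    67.5 and 135 mM; interpolation is linear in log-concentration and
    clamped outside the tabulated range.
    """
    if conc_mm <= 0:
        raise ValueError("concentration must be > 0")
    c = np.log10([row[0] for row in NACL_ACTIVITY_TABLE])
    g = [row[1] for row in NACL_ACTIVITY_TABLE]
    return float(np.interp(np.log10(conc_mm), c, g))


@dataclass(frozen=True)
class Ion:
    concentration_mm: float
    valence: int
    activity_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration_mm < 0:
            raise ValueError("concentration must be >= 0")
        if not 0 < self.activity_coefficient <= 1:
            raise ValueError("activity coefficient must be in (0, 1]")

    @property
    def activity_mm(self) -> float:
        return self.concentration_mm * self.activity_coefficient


@dataclass(frozen=True)
class IonicConditions:
    """Apical/basolateral ion tables (mM) plus temperature (K).

    Only monovalent ions enter the GHK algebra; minor divalent buffer
    components are ignored, as is conventional for NaCl-dominated
    solutions.
    """

    apical: dict[str, Ion] = field(default_factory=dict)
    basolateral: dict[str, Ion] = field(default_factory=dict)
    temperature_k: float = T_BODY

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")

    def activity(self, ion: str, side: str) -> float:
        table = self.apical if side == "apical" else self.basolateral
        return table[ion].activity_mm if ion in table else 0.0

    def swapped(self) -> "IonicConditions":
        return replace(self, apical=self.basolateral, basolateral=self.apical)

    def thermal_mv(self) -> float:
        return 1000.0 * R_GAS * self.temperature_k / FARADAY


@dataclass
class PermeabilityResult:
    p_na_over_p_cl: float | None = None
    p_x_over_p_na: dict[str, float] = field(default_factory=dict)
    absolute_p_na_cm_s: float | None = None


def _nacl_side(conc_mm: float) -> dict[str, Ion]:
    g = activity_coefficient_nacl(conc_mm)
    return {"Na": Ion(conc_mm, 1, g), "Cl": Ion(conc_mm, -1, g)}


def hbss(
    apical_nacl_mm: float = 135.0,
    basolateral_nacl_mm: float = 135.0,
    temperature_k: float = T_BODY,
) -> IonicConditions:
    """NaCl-dominated saline on both sides (dilutions via the arguments).

    A 90% apical dilution corresponds to ``apical_nacl_mm=13.5``; the
    osmotic balance (mannitol replacement) carries no charge and is not
    represented.
    """
    return IonicConditions(
        _nacl_side(apical_nacl_mm), _nacl_side(basolateral_nacl_mm), temperature_k
    )


def biionic_conditions(
    cation: str,
    substituted_nacl_mm: float = 135.0,
    temperature_k: float = T_BODY,
) -> IonicConditions:
    """Basolateral NaCl fully replaced by XCl at equal concentration.

    The substituted salt is assigned the NaCl activity coefficient at
    the same concentration (the conventional approximation for these
    monovalent chlorides).
    """
    g = activity_coefficient_nacl(substituted_nacl_mm)
    baso = {cation: Ion(substituted_nacl_mm, 1, g), "Cl": Ion(substituted_nacl_mm, -1, g)}
    return IonicConditions(_nacl_side(substituted_nacl_mm), baso, temperature_k)


def ghk_vrev(conditions: IonicConditions, permeabilities: dict[str, float] | float) -> float:
    """GHK reversal potential (mV), V = V_apical − V_basal.

    ``permeabilities`` maps ion name to permeability relative to Na
    (Na defaults to 1).  Passing a bare number is shorthand for a
    Na/Cl system with that P_Na/P_Cl ratio.
    """
    if isinstance(permeabilities, (int, float)):
        if permeabilities <= 0:
            raise ValueError("P_Na/P_Cl must be > 0")
        perms = {"Na": 1.0, "Cl": 1.0 / float(permeabilities)}
    else:
        perms = dict(permeabilities)
        perms.setdefault("Na", 1.0)
    num = 0.0
    den = 0.0
    ions = set(conditions.apical) | set(conditions.basolateral) | set(perms)
    for name in ions:
        p = perms.get(name, 0.0)
        if p == 0.0:
            continue
        z = None
        for side in (conditions.apical, conditions.basolateral):
            if name in side:
                z = side[name].valence
                break
        if z not in (1, -1):
            raise ValueError(f"GHK voltage equation needs monovalent ions ({name})")
        a_api = conditions.activity(name, "apical")
        a_baso = conditions.activity(name, "basolateral")
        if z == 1:
            num += p * a_baso
            den += p * a_api
        else:
            num += p * a_api
            den += p * a_baso
    if den == 0:
        raise ValueError("zero GHK denominator")
    return conditions.thermal_mv() * float(np.log(num / den))


def invert_ghk_dilution(v_rev_mv: float, conditions: IonicConditions) -> float:
    """P_Na/P_Cl from a dilution-potential measurement (closed form).

    Solving the two-ion GHK equation for the ratio r = P_Na/P_Cl:
    with E = exp(V_rev·F/RT),
    r = (a_Cl,api − E·a_Cl,baso) / (E·a_Na,api − a_Na,baso).
    The solution is unique and monotone in V_rev; V_rev outside the
    Nernst limits of the two ions has no positive solution.
    """
    a_na_a = conditions.activity("Na", "apical")
    a_na_b = conditions.activity("Na", "basolateral")
    a_cl_a = conditions.activity("Cl", "apical")
    a_cl_b = conditions.activity("Cl", "basolateral")
    if a_na_a == a_na_b and a_cl_a == a_cl_b:
        raise ValueError("conditions are symmetric; the ratio is unidentifiable")
    e = float(np.exp(v_rev_mv / conditions.thermal_mv()))
    num = a_cl_a - e * a_cl_b
    den = e * a_na_a - a_na_b
    if den == 0 or num / den <= 0:
        raise ValueError("V_rev outside the Nernst bounds; no positive solution")
    return num / den


def biionic_px_over_pna(
    v_rev_mv: float,
    conditions: IonicConditions,
    cation: str,
    p_na_over_p_cl: float,
) -> float:
    """P_X/P_Na from a biionic reversal potential (closed form).

    Basolateral Na is replaced by the test cation X; with P_Na = 1 and
    P_Cl = 1/(P_Na/P_Cl) known, the GHK equation is linear in P_X.
    """
    if p_na_over_p_cl <= 0:
        raise ValueError("P_Na/P_Cl must be > 0")
    p_cl = 1.0 / p_na_over_p_cl
    e = float(np.exp(v_rev_mv / conditions.thermal_mv()))
    a_x_b = conditions.activity(cation, "basolateral")
    if a_x_b == 0:
        raise ValueError(f"no basolateral {cation} in the conditions")
    num = e * (
        conditions.activity("Na", "apical")
        + conditions.activity(cation, "apical")  # 0 under full substitution
        + p_cl * conditions.activity("Cl", "basolateral")
    ) - (conditions.activity("Na", "basolateral") + p_cl * conditions.activity("Cl", "apical"))
    p_x = num / a_x_b
    if p_x < 0:
        raise ValueError("V_rev outside the attainable range; no positive solution")
    return p_x


def kimizuka_koketsu_pna(
    ter_ohm_cm2: float,
    p_na_over_p_cl: float,
    conditions: IonicConditions | None = None,
    na_conc_mm: float = 135.0,
) -> float:
    """Absolute Na⁺ permeability (cm/s) from TER and P_Na/P_Cl.

    P_Na = (RT/F²)·G·[r/(1+r)]/a_Na with G = 1/TER in S/cm² and a_Na
    the bulk Na activity in mol/cm³.  Linear in conductance; tends to
    (RT/F²)·G/a_Na as the junction becomes perfectly cation-selective.
    """
    if ter_ohm_cm2 < 0:
        raise ValueError("TER must be >= 0")
    if p_na_over_p_cl < 0:
        raise ValueError("permeability ratio must be >= 0")
    if conditions is not None:
        t = conditions.temperature_k
        a_na_mm = conditions.activity("Na", "basolateral") or conditions.activity("Na", "apical")
    else:
        t = T_BODY
        a_na_mm = na_conc_mm * activity_coefficient_nacl(na_conc_mm)
    if a_na_mm <= 0:
        raise ValueError("Na activity must be > 0")
    if ter_ohm_cm2 == 0:
        raise ValueError("TER must be > 0")
    g = 1.0 / ter_ohm_cm2  # S/cm²
    a_na = mm_to_mol_per_cm3(a_na_mm)  # mol/cm³
    fraction = p_na_over_p_cl / (1.0 + p_na_over_p_cl) if np.isfinite(p_na_over_p_cl) else 1.0
    return (R_GAS * t / FARADAY**2) * g * fraction / a_na
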
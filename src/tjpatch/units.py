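"""Physical constants and the package-wide unit conventions.

Units are fixed across the package: currents in pA, voltages in mV,
conductances in pS, resistances in GΩ (areal resistances in Ω·cm²),
times in s (dwell times reported in ms where conventional),
concentrations in mM, temperatures in K.

Handy identities under these conventions:

* ``I[pA] = g[pS] * V[mV] / 1000``
* ``I[pA] = V[mV] / R[GΩ]``
"""

#: Gas constant, J·mol⁻¹·K⁻¹.
R_GAS = 8.314462618

#: Faraday constant, C·mol⁻¹.
FARADAY = 96485.33212

#: Default experimental temperature (37 °C), K.
T_BODY = 310.15

PS_PER_NS = 1000.0
MS_PER_S = 1000.0


def thermal_voltage(temperature_k: float = T_BODY) -> float:
    """RT/F in mV (≈26.7 mV at 37 °C)."""
    return 1000.0 * R_GAS * temperature_k / FARADAY


def current_pa(conductance_ps: float, v_mv: float, v_rev_mv: float = 0.0) -> float:
    """Ohmic single-channel current in pA for a conductance in pS."""
    return conductance_ps * (v_mv - v_rev_mv) / PS_PER_NS


def mm_to_mol_per_cm3(conc_mm: float) -> float:
    """Convert mM (mmol/L) to mol/cm³."""
    return conc_mm * 1e-6
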
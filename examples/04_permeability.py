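"""Charge selectivity and absolute Na+ permeability from potentials.

Converts a dilution-potential measurement into P_Na/P_Cl with the GHK
voltage equation, a biionic potential into P_X/P_Na, and combines TER
with P_Na/P_Cl into an absolute Na+ permeability by the
Kimizuka–Koketsu relation.
"""
from tjpatch.permeability import (
    biionic_conditions,
    biionic_px_over_pna,
    ghk_vrev,
    hbss,
    invert_ghk_dilution,
    kimizuka_koketsu_pna,
)

# 90% apical NaCl dilution (135 -> 13.5 mM, mannitol-balanced)
diluted = hbss(apical_nacl_mm=13.5)
v_rev = ghk_vrev(diluted, 9.5)   # forward model at the cation-selective ratio
ratio = invert_ghk_dilution(v_rev, diluted)
print(f"dilution potential {v_rev:.1f} mV  ->  P_Na/P_Cl = {ratio:.2f}")

# biionic: basolateral Na+ fully replaced by methylamine (MA+)
bc = biionic_conditions("MA")
p_ma = biionic_px_over_pna(0.5, bc, "MA", p_na_over_p_cl=9.5)
print(f"biionic V_rev 0.5 mV ->  P_MA/P_Na = {p_ma:.2f} (near 1: MA+ permeates like Na+)")

# absolute Na+ permeability from TER by Kimizuka–Koketsu
p_na = kimizuka_koketsu_pna(ter_ohm_cm2=100.0, p_na_over_p_cl=9.5)
print(f"TER 100 Ohm.cm2, P_Na/P_Cl 9.5  ->  P_Na = {p_na:.3g} cm/s")
print("A P_Na/P_Cl near 10 marks a strongly cation-selective junction; "
      "V_rev of a large test cation shifts negative when it permeates poorly.")
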
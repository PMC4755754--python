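"""Equivalent-circuit arithmetic for the patch configuration.

Every current pathway seen by the pipette is an ohmic resistor.  Under
the package's unit conventions mV/pA = GΩ, so the measured event
amplitudes at 100 mV translate directly into pathway resistances.
"""
from tjpatch.circuit import (
    CircuitModel,
    areal_to_absolute,
    combine_pathways,
    ohmic_resistance,
    round_sig,
)

for label, amp in [("claudin-2 channel", 9.0), ("independent channel", 4.0),
                   ("apical membrane path", 2.0), ("seal leak", 3.5)]:
    r = ohmic_resistance(amp, 100.0)
    print(f"{label:22s}: {amp:4.1f} pA @ 100 mV  ->  {round_sig(r, 2):g} GOhm")

shunt = areal_to_absolute(1500.0, 0.33)
print(f"monolayer shunt       : 1500 Ohm.cm2 / 0.33 cm2 = {round_sig(shunt, 2):g} MOhm")

c = CircuitModel()
series = combine_pathways([c.resistances["electrode"], c.resistances["cldn2_channel"]], "series")
print(f"electrode + channel   : {series:.4f} GOhm (electrode is negligible)")
print("The sub-MOhm monolayer shunt and MOhm electrode cannot shape the "
      "GOhm-scale single-channel events: detected currents cross the junction.")
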
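"""Reversal potential and conductance from voltage ramps.

Simulates repeated 1 s ramps from −100 to +100 mV (oversampled at
100 kHz, block-averaged to 10 kHz), subtracts the mean event-free sweep
from sweeps that contain openings, and fits the pooled open-channel
samples with a line.  The slope is the single-channel conductance and
the zero crossing the reversal potential.
"""
import numpy as np

import tjpatch as tj
from tjpatch.protocol import ramp_protocol
from tjpatch.ramps import RampSet, block_average, fit_iv, subtract_baseline_ramps
from tjpatch.recording import RecordingConfig, render_current

# frequent opener (same 90 pS pore) so the I-V cloud spans the ramp
model = tj.claudin2_model(tau_open_s=5e-3, tau_closed_transient_s=2e-3,
                          tau_closed_stable_s=0.5, p_terminate=0.2)
proto = ramp_protocol()
ss = np.random.SeedSequence(3)
sweeps = []
for _ in range(40):
    s = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    path = tj.simulate_state_path(model, 1.0, s)
    cfg = RecordingConfig(sampling_rate=100_000.0, oversample=1,
                          duration=1.0, rng_seed=s + 1)
    sweeps.append(block_average(render_current([path], proto, cfg), 10))

v, i = subtract_baseline_ramps(RampSet(sweeps))
res = fit_iv(v, i)
print(f"slope conductance  : {res.slope_conductance:.1f} pS")
print(f"reversal potential : {res.v_rev:.2f} mV")
print(f"fit residual       : {res.fit_residual:.2f} pA RMS over {v.size} samples")
print("A ~90 pS linear I-V reversing at ~0 mV in symmetric solutions is the "
      "signature of a passive paracellular channel.")
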
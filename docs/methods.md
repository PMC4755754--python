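# Methods

## The gating model

Claudin-2 channel gating is modelled as a continuous-time Markov chain with
one open and two closed states. The paracellular channel literature
constrains the *number* of states (single-exponential open durations,
double-exponential closed durations) and bounds on the time constants
(τ_open < 1 ms, τ_closed,transient < 2 ms, τ_closed,stable > 1 s), but not
the connectivity. We adopt the linear scheme

```
c_stable  ↔  o  ↔  c_transient
```

because it is the simplest topology that produces the observed bursting:
runs of o/c_transient flicker terminated by entry into c_stable. Defaults:
τ_open = 0.6 ms, τ_c,transient = 1.2 ms, τ_c,stable = 3 s, and a burst
termination probability of 0.1 per closure (so bursts contain a geometric
mean of 10 openings and detected closed durations are a 0.9/0.1 mixture of
the transient and stable components). All rates are configurable; the
topology is a constructor argument, not an assumption baked into the
analysis code. Sojourns are simulated with the Gillespie algorithm; the
stationary occupancy used for initialization and for verification is the
null vector of the generator matrix.

The claudin-2-independent ~4.3 pA class is a two-state channel
(τ_open = 1.5 ms, τ_closed = 0.4 s, 43 pS); the off-junction apical-membrane
class is a 15 pS two-state channel with 8 ms openings whose opening rate is
four-fold higher at +100 mV than −100 mV, matching its observed voltage
asymmetry. Neither choice affects the claudin-2 analyses; they exist so that
classification and filtering steps face realistic confounders.

## Rendering

Instantaneous patch current is Σ_open γ·(V − V_rev)/1000 + V/R_seal plus
Gaussian noise, in pA with γ in pS, V in mV and R_seal in GΩ. Negative
current means cations flowing toward the recording electrode, so an open
90 pS channel at −100 mV gives −9 pA. The amplifier's analog low-pass is
represented by a 4-pole digital Bessel filter (−3 dB at 5 kHz by default;
the true analog response is unknowable, and a Bessel filter is the standard
patch-clamp choice because of its flat group delay). Rendering happens at
2× the output rate and is decimated after filtering. Injected white noise
is scaled by the filter's white-noise gain so that the *filtered* baseline
RMS equals `noise_sd` (default 0.6 pA) regardless of cutoff: with that
default, 4 pA events are cleanly resolvable at 5 kHz while sub-2 pA
off-junction events require re-filtering to 500 Hz, as in practice.
Identical seeds give bit-identical traces.

## Scenarios

Channel counts are not observable in patch data; only expression-
proportional NPo is. We use 8 claudin-2 channels for the induced/control
condition and 1 for suppression/knockdown, making the expected NPo ratio
exactly 1/8 (an ~87.5% reduction). Cooling is phenomenological: a
temperature scale of 0.63 multiplies all gating rates (slower kinetics,
unchanged per-channel open probability) and the active channel count
(8 → 5), reducing NPo and event counts by ~37% while leaving amplitudes
untouched; no Arrhenius model is fitted. La³⁺ block deactivates all
claudin-2 channels at the onset time (a step, since the block is complete
on the solution-exchange timescale); MTSET derivatization of the I66C pore
mutant deactivates each channel after an exponential delay with a 7 s time
constant, so detectable events disappear over ~20 s. The independent 4 pA
class is cold- and inhibitor-resistant and never blocked.

## Idealization

Baseline is the mode of the sample density on a 0.1 pA grid (refined by the
mean of samples within ±0.5 pA), falling back to the median with a warning
when no level holds 30% of samples. Events are detected by the classical
half-amplitude criterion: baseline-subtracted samples are quantized to the
nearest integer multiple of the unitary amplitude, which both places the
open threshold at 50% and resolves multi-channel levels at integer
multiples. Runs shorter than the dead time (default 0.2 ms, set by the
5 kHz filter risetime) are merged into the dominant neighbour. Event
amplitude is the mean of within-event samples excluding two samples at each
edge (filter transients). No missed-event correction is applied. Whether
seal-leak current should be subtracted before amplitude measurement is
ambiguous in practice; we always subtract the estimated baseline, which
removes the leak at a constant holding potential.

The ~9 pA claudin-2-dependent and ~4.3 pA independent classes are separated
by per-event mean amplitude at 6 pA, the midpoint between the class centers
at ±100 mV. NPo is computed exactly as Σ(open time × number of channels
open)/total record time.

## Dwell-time fitting

Dwell-time fits use raw (unbinned) durations by maximum likelihood;
log-spaced histograms (2 bins per decade) are display-only. Binned-ML and
raw-ML estimators agree in the fine-bin limit, and the raw form is better
posed for sparse, seconds-long closed dwells. Durations are shifted by the
detection dead time before fitting: left truncation of an exponential
mixture preserves every component's τ under this shift, so τ estimates stay
consistent despite censoring (component fractions refer to *detected*
events). The single-exponential ML estimate is the sample mean in closed
form; two-component fits use EM from five deterministic quantile-based
starts. One versus two components is decided by a likelihood-ratio test at
α = 0.01 against χ²₂ (two extra parameters); a component with vanishing
weight collapses the state count. Boundary dwells (first/last of a record)
are excluded. Dead-time-censored likelihood corrections and full Q-matrix
fitting are deliberately out of scope.

Amplitude histograms are fitted by weighted EM on the binned counts (the ML
problem for binned data), with five deterministic multi-starts spread over
the occupied range and standard deviations floored at the 0.1 pA bin width
(hitting the floor flags the fit as degenerate).

## Ramp analysis

Sweeps are classified open/event-free by the same half-amplitude criterion
with a voltage-scaled threshold γ·(V−V_rev)/2000, ignoring the region where
the expected unitary amplitude falls below 2 pA. The mean event-free sweep
is subtracted pointwise from event-containing sweeps; pooled open samples
are fitted by least squares, giving the slope conductance (pS) and the zero
crossing (V_rev). Ramps rendered at 100 kHz are decimated by 10-sample
block averaging to 10 kHz, trading bandwidth for noise exactly as in the
oversampled acquisition the method emulates.

## Permeability algebra

Only Na⁺, Cl⁻ and one substituted monovalent cation enter the GHK voltage
equation; minor buffer ions are neglected and liquid-junction potentials
set to zero. Activities use mean NaCl coefficients 0.755/0.812/0.882 at
135/67.5/13.5 mM, log-linearly interpolated in concentration elsewhere
(activities rather than concentrations are the default throughout, with
the coefficients exposed for callers who prefer otherwise). The convention
is V = V_apical − V_basal at 310.15 K. Both the dilution inversion
(P_Na/P_Cl) and the biionic inversion (P_X/P_Na) are closed-form — the GHK
equation is a Möbius function of the unknown ratio — and both raise when
the measured V_rev lies outside the attainable Nernst bounds. Absolute Na⁺
permeability uses the Kimizuka–Koketsu transference-fraction form
P_Na = (RT/F²)·G·[r/(1+r)]/a_Na (G = 1/TER in S/cm², a_Na in mol/cm³),
verified against its limiting cases (linear in G; → (RT/F²)·G/a_Na as the
junction becomes perfectly cation-selective).

## Circuit conventions

All pathways are ohmic. Units are chosen so arithmetic is direct:
mV/pA = GΩ; Ω·cm² divided by cm² gives Ω. Reported resistances follow the
2-significant-figure convention (1 s.f. for the seal leak). The monolayer
shunt outside the pipette (100–1500 Ω·cm² ⇒ 0.0003–0.0045 MΩ on a 0.33 cm²
support) is so much smaller than any GΩ pathway that it is effectively a
short circuit in the model.

## Statistics

Group comparisons use Welch's unequal-variance t-test; multiple comparisons
use Holm–Bonferroni step-down adjustment (delegated to scipy/statsmodels).
Replicate summaries report mean ± SEM.

## What the simulator does and does not capture

The generator reproduces the statistical structure of trans-junction
recordings: amplitudes, gating time constants, bursting, class mixtures,
seal leak, filtering and noise levels, block and cooling phenomenology. It
does not model amplitude variability between patches ("~5 to >10 pA"),
capacitive transients, drift, real solution-exchange artifacts, strand
architecture, or the chemistry of MTSET/La³⁺ — the last two are represented
purely as channel-deactivation schedules. Passing tests therefore
demonstrate that the *analysis chain* is correct and self-consistent under
realistic conditions, not that any particular biological parameter value is
re-measured from laboratory data; population quantities from real tissue
(e.g. P_Na/P_Cl of 7.4 measured on single-channel events) enter only as
input parameters where needed.

## Problem sizes and determinism

Dwell-time state counting uses 400–500 s of simulated single-channel
recording (~800–1200 events, ~150 visits to the stable closed state);
NPo comparisons use 8 replicates of 30 s; the cooling comparison, whose
effect size is smaller, uses 16 replicates of 120 s per condition; ramp
I-V uses 40 one-second sweeps. These sizes put the Monte-Carlo error of
each summary comfortably below the effect being measured. Every stochastic
step descends from a single `numpy` `SeedSequence`, so identical seeds give
identical tables bit for bit.

## Known limitations

- No hidden-Markov or segmental-k-means idealization; heavily overlapping
  multi-channel records are resolved only on the integer amplitude grid.
- No dead-time (missed event) likelihood correction; τ estimates for the
  fast components are biased upward by roughly the dead time (~0.2 ms) plus
  brief-closure merging, which keeps them inside the documented bounds but
  should not be read as unbiased rate estimates.
- The GHK layer handles monovalent ions only; divalents (Ca²⁺, Mg²⁺,
  La³⁺) are outside its scope.
- ABF ingestion is not included; traces exchange as TSV with a JSON
  sidecar.
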
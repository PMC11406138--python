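# Methods

## Model formulation and units

A neuron soma is one cylindrical compartment. Membrane area is the lateral
cylinder surface π·d·L (no end caps), matching the convention of
compartmental simulators. Units are mV, ms, S/cm², µF/cm² and mA/cm²
throughout; stimulus currents are given in pA and divided by the membrane
area. With those units the voltage equation is
dV/dt = 1000·(I_stim/A − ΣI_ion)/C_m mV/ms.

Axial resistivity is stored with the geometry but has no physical effect in
a single compartment; it is retained so model files can record the full
published parameter set. (Published DRG models quote "1 Ω/cm"; the
conventional unit is Ω·cm and the field is named accordingly.)

Ion concentrations are fixed for the whole simulation: reversal potentials
are computed once by the Nernst equation and never updated. Temperature
(default 32 °C) enters only through the Nernst factor RT/zF; gate kinetics
are used exactly as published, with no Q10 rescaling — this mirrors the
behaviour of the original simulator configuration, where the temperature
parameter is recorded but unused by the mechanisms.

## Declarative gate kinetics

Each gating variable is defined by a functional form plus coefficients in
the model YAML file:

* `alpha_beta` — HH rate pair; rate kinds `exp` (a·e^{(v−b)/c}),
  `explinear` (a·(v−b)/(1−e^{−(v−b)/c}), with the analytic limit a·c at the
  removable singularity) and `sigmoid` (a/(1+e^{−(v−b)/c})); optional
  `tau_min` floor.
* `inf_tau` — steady state as `boltzmann` (1/(1+e^{(V½−v)/k})) or
  `constant`, time constant as `constant`, `bell`
  (base + amp/(e^{(v−v₁)/k₁}+e^{−(v−v₂)/k₂})) or `gaussian`.

These forms cover the common parameterisations of voltage-gated channel
models, so transcribing published kinetics is a data-entry task. The
published eight-current hDRG kinetics live in that model's data supplement
and are deliberately not bundled; `models/hdrg_template.yaml` names the
currents and the fields to fill in.

## Integration

The ODE system is solved with LSODA (adaptive, stiff-capable) via
`scipy.integrate.odeint`, with rtol 1e−7 / atol 1e−8 defaults. Stimulus
on/off times are passed as critical points so no step straddles a
discontinuity. Gate x_∞/τ curves are tabulated once per model on a
−150..+100 mV grid at 0.02 mV and evaluated by linear interpolation inside
the right-hand side; the kernel is JIT-compiled with numba when available
(a pure-numpy kernel with identical semantics is the fallback, and a test
pins the tabulated kernel against the exact closure-based `rhs()` at random
states). Solutions are recorded on a uniform 40 kHz grid and then decimated
by two to 20 kHz — record-then-downsample, in that order. Recorded gate
values are clipped to [0, 1] to guard against solver overshoot at the 1e−9
level; per-current densities, when requested, are reconstructed from the
recorded gates.

During a rheobase scan the pre-stimulus segment does not depend on the
scanned amplitude, so it is integrated once per model and re-used
(`ModelRunner`). A fixed-step RK4 integrator (`reference.py`, dt 0.001 ms)
provides an independent integration path for cross-checks.

## Protocols and rheobase

Step and ramp current-clamp protocols use the standard defaults: 500 ms
delay, 800 ms (step) / 500 ms (ramp) duration, 1500 ms total, −65 mV
initialisation. The 500 ms pre-stimulus delay doubles as the settling
period. Rheobase scans 100 pA increments from 100 pA to 5000 pA and returns
the first amplitude with a detected AP; 0 pA is not simulated because a
zero stimulus cannot evoke a stimulus-driven AP. Ramp "rheobase" is the
ramp's final amplitude, the only scalar available. Because a ramp charges
the membrane more gently than a step, the ramp trace used for threshold
measurement is taken at the ramp's own rheobase, found by the same scan.

## AP detection and biomarkers

The AP detector is an upward crossing of a fixed level (0 mV), with the
event open until the voltage returns below the level. An event that has not
closed by the end of the trace still counts — this is required for
depolarisation-block accounting, and it means a membrane driven
monotonically across 0 mV (e.g. a nearly passive cell under extreme
current) registers a detection; calibration rejects such candidates by
their biomarkers.

Biomarkers follow the experimental definitions: threshold voltage is where
the centred-difference dV/dt first exceeds 5 mV/ms on the first ramp AP's
upstroke; slopes are gradient extrema over a window extended from the
pre-upstroke minimum to the post-AP trough (the true maximum slope occurs
below the detection level); widths interpolate level crossings linearly
between samples; half width is the longest continuous period above the
midpoint of threshold and peak; the AHP is fit with A·e^{−t/τ}+c from the
post-peak minimum until the gradient exceeds 5 mV/ms or 50 ms elapse
(initialised A = V_start−V_end, c = V_end, τ = window/5; windows under 10
samples or non-positive fitted τ are flagged); RMP is the minimum of the
last ⌊n/10⌋ samples (at least one) of a zero-stimulus run; firing rate
counts AP peaks inside the stimulus window divided by the stimulus duration.
Step-trace widths use the ramp-derived threshold, and all per-AP biomarkers
come from the *first* AP of the at-rheobase step trace (at rheobase
typically only one AP fires). Any unmeasurable biomarker is NaN plus a
validity flag, never silently zero.

## Population calibration

Candidates are Latin hypercube samples (scipy's LHS; exactly one sample per
equal-width bin per parameter) of all conductance scalings, by default over
[0, 2]× baseline for every current — the headline design. (The original
tool also documents per-parameter dictionaries with wider ranges; those are
supported as explicit `SamplingRanges`.) Default candidate count is 20,000.
Acceptance requires every calibrated biomarker inside mean ± 1.5·SD with
*inclusive* bounds (inclusivity avoids float-equality pathologies);
flagged biomarkers reject; candidates whose simulation fails outright are
recorded as failures and treated as rejected. Provenance (seed, ranges,
calibration, protocol parameters, yields, engine version) is stored with
the population, and results are independent of evaluation order and worker
count.

## Grid experiments

A `GridDesign` crosses per-conductance factor lists with stimulus
amplitudes; cell factors multiply onto each model's own stored factors
(scaling composition is exact, by linearity of ḡ in the current equation).
The four-parameter design — amplitudes 0–6000 pA in 1000 pA steps, three
conductances 0–2 in 0.5 steps — enumerates 875 cells. Models failing in a
cell are excluded from that cell's mean (with counts reported), not
zero-filled. The rapid-firing split counts cells above 20 AP/s per model,
ranks descending with ties broken by stable model order, and takes the top
⌈25 %⌉. Repolarisation failure is declared when, after the last AP peak,
the voltage does not return below the detection level before stimulus
offset (the experimental literature describes the phenomenon but not a
criterion; this one is explicit and testable).

## Currentscape

Each current is classified by its instantaneous sign at each sample
(outward positive); a sign-switching current contributes to either side at
different times. Fractions are |I_i|/Σ|I_j| over same-sign currents;
samples where a side's total is zero have undefined fractions (NaN,
rendered as gaps rather than fabricated shares). Normalisation,
scale-invariance and net-current bookkeeping are asserted invariants.

## Synthetic fixtures and what passing means

The toy model is the classic squid-axon triple (fast Na, delayed-rectifier
K, leak) on the DRG-soma geometry, expressed through the same declarative
machinery as any transcribed model. It exercises every code path —
spiking, rheobase, calibration, grids, currentscapes — but its kinetics are
not DRG kinetics: passing the suite demonstrates engine and pipeline
correctness, not that hDRG-specific numbers are reproduced. The synthetic
spike generator produces piecewise-linear/exponential APs (slow foot below
5 mV/ms, fast rise, linear fall, exponential AHP) whose biomarkers are
known in closed form; it validates the extractors independently of any ODE.
Synthetic calibration ranges default to a 20 % relative SD on the eight
calibration biomarkers (half width and firing rate are measured but not
calibrated on), which is in the range of between-neuron coefficients of
variation reported for sensory-neuron AP biomarkers; with ±1.5 SD bounds
the toy population accepts roughly 4–5 % of candidates over the full
[0, 2]³ sampling cube.

## Problem sizes

The end-to-end smoke uses 200 LHS candidates with the full-length default
protocols, a 3 × 3 grid and one rendered currentscape (~2–3 minutes on one
CPU); unit tests use shortened protocols (20 ms delay, 100–200 ms stimuli)
because the toy model settles within a few ms. The acceptance script runs
the same 200-candidate pipeline.

## Known limitations

Single compartment only (no axon/cable, hence stored-but-unused axial
resistivity); no calcium currents, pumps or ion accumulation; no voltage
clamp; no temperature-dependent kinetics; the AP detector is a fixed-level
crossing, appropriate for overshooting APs only. Reproducing the published
hDRG population requires user-supplied transcription of the supplement's
channel kinetics and the experimental calibration table.
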
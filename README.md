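# popneuron

Population-of-models simulation of human dorsal root ganglion (hDRG) neuron
action potentials.

## The problem

Sensory neurons of the dorsal root ganglion transmit pain signals, and their
excitability depends on the balance of many ionic currents — most notably the
sodium channel Nav 1.8 and the delayed-rectifier (IKdr) and M-type (IKM)
potassium currents. Real neurons vary widely in how much of each channel they
express, so the effect of blocking or enhancing one conductance depends on the
background of all the others. `popneuron` implements the *population of
models* methodology for studying this: instead of one hand-tuned model, it
builds an ensemble of models that share equations but differ in conductances,
keeps only those whose simulated action potentials (APs) match experimental
variability, and then runs channel-block experiments across the whole
ensemble.

It is aimed at computational neuroscientists and pharmacology modellers who
want an open, scriptable, NEURON-free engine for single-compartment
conductance-based models with experimentally calibrated variability.

## The model

The soma is a single cylindrical compartment (length 30 µm, diameter 46 µm,
specific capacitance C_m = 1 µF/cm²) with Hodgkin–Huxley currents

    I_i = s_i · ḡ_i · ∏_j x_j^{p_j} · (V − E_i),     dx_j/dt = (x_∞(V) − x_j)/τ_x(V)

    C_m dV/dt = I_stim/A − Σ_i I_i

where s_i is a dimensionless per-current scaling factor (1 = baseline,
0 = full block), ḡ_i a maximal conductance in S/cm², and E_i either a fixed
reversal or a Nernst potential from fixed ion concentrations
([Na]_o/i = 145/5 mM, [K]_o/i = 3/135 mM, 32 °C). Gate kinetics are
*declarative*: each gate is a small parameter block (Boltzmann / rate-pair /
bell-shaped forms) in a YAML model file, so published channel models can be
transcribed without touching code. The package ships a classic three-current
toy model (`popneuron/models/toy_hh.yaml`) wired through exactly the same
machinery, plus an annotated eight-current hDRG template
(`hdrg_template.yaml`) awaiting transcription of the published kinetics.

The pipeline:

1. **Rheobase** — step simulations at 100 pA increments (up to 5 nA) until
   the first detected AP.
2. **Biomarkers** — threshold voltage (where dV/dt first exceeds 5 mV/ms on a
   ramp), peak voltage, max/min dV/dt, full width at threshold, AHP time
   constant (single-exponential fit, ≤ 50 ms window), resting membrane
   potential (min of the last 10 % of a zero-stimulus run), rheobase — plus
   AP half width and firing rate.
3. **Population** — Latin hypercube sampling of all conductance scalings over
   0–2× baseline; a candidate is accepted iff every calibrated biomarker lies
   within mean ± 1.5 SD of the experimental range.
4. **Experiments** — factorial grids of scaling factors × stimulus
   amplitudes over the whole population (e.g. the 7 × 5 × 5 × 5 = 875-cell
   four-parameter design), with mean-rate aggregation, rapid-firing
   population splits and repolarisation-failure detection.
5. **Currentscape** — per-timepoint fractional decomposition of total inward
   and outward current, rendered as stacked share plots.

Simulations integrate with an adaptive stiff-capable solver (LSODA), are
sampled at 40 kHz and down-sampled to 20 kHz, matching patch-clamp
acquisition conventions.

## Worked example

```python
import popneuron as pn

model = pn.toy_hh_model()
rheo = pn.find_rheobase(model, pn.step_protocol())
print(rheo.amplitude)        # 100.0  (pA; first 100 pA multiple that spikes)

bset = pn.evaluate_candidate(model, {})
print(round(bset.threshold_voltage, 1),  # -52.9 mV
      round(bset.peak_voltage, 1),       # 34.5  mV
      round(bset.full_width, 2),         # 2.99  ms
      round(bset.ahp_tau, 2))            # 5.28  ms
```

`evaluate_candidate` searched the step and ramp rheobases, simulated the
model at both, and measured every biomarker: the toy neuron fires at 100 pA,
crosses its 5 mV/ms threshold at −52.9 mV, peaks at +34.5 mV, stays above
threshold for 2.99 ms, and its after-hyperpolarisation relaxes with a 5.3 ms
time constant.

A full toy pipeline (population → grid → currentscape) is one command:

```bash
popneuron demo --out demo_run --n-candidates 200 --seed 1
```

which builds a 200-candidate population calibrated around the baseline
biomarkers (accepting ~4–5 % of candidates), runs a 3 × 3
Nav-scaling × amplitude grid and renders a currentscape. The other CLI verbs
are `build-pop`, `run` (YAML run configs), `run-grid`, `biomarkers` and
`currentscape`.

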
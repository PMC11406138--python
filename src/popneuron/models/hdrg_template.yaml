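# Template for the eight-current human DRG soma model.
#
# The published gating equations and conductance densities for these
# currents live in the model's data supplement; transcribe them here (gbar
# in S/cm^2, one gate block per gating variable using the declarative
# kinetics forms: alpha_beta with exp/explinear/sigmoid rates, or inf_tau
# with boltzmann/constant steady states and constant/bell/gaussian time
# constants).  Loading this file untranscribed (gbar: null) raises a clear
# error.
name: hdrg_soma
geometry:
  length_um: 30.0
  diameter_um: 46.0
  axial_resistivity_ohm_cm: 1.0   # stored; no effect in one compartment
  capacitance_uf_cm2: 1.0
concentrations:
  na_out_mm: 145.0
  na_in_mm: 5.0
  k_out_mm: 3.0
  k_in_mm: 135.0
  temperature_c: 32.0
currents:
  - name: Nav1.7
    gbar: null
    reversal: "nernst:na"
    gates: []
  - name: Nav1.8
    gbar: null
    reversal: "nernst:na"
    gates: []
  - name: Nav1.9
    gbar: null
    reversal: "nernst:na"
    gates: []
  - name: Kdr
    gbar: null
    reversal: "nernst:k"
    gates: []
  - name: KA
    gbar: null
    reversal: "nernst:k"
    gates: []
  - name: KM
    gbar: null
    reversal: "nernst:k"
    gates: []
  - name: Kleak
    gbar: null
    reversal: "nernst:k"
    gates: []
  - name: H
    gbar: null
    reversal: -30.0   # mixed cation current; fixed reversal, fill from source
    gates: []
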
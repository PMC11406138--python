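# Classic squid-axon Hodgkin-Huxley model (fast Na, delayed-rectifier K,
# leak) mounted on the DRG-soma geometry.  Ships with the package so the
# whole pipeline is testable without any transcribed channel kinetics.
name: toy_hh
geometry:
  length_um: 30.0
  diameter_um: 46.0
  axial_resistivity_ohm_cm: 1.0
  capacitance_uf_cm2: 1.0
concentrations:
  na_out_mm: 145.0
  na_in_mm: 5.0
  k_out_mm: 3.0
  k_in_mm: 135.0
  temperature_c: 32.0
currents:
  - name: NaT
    gbar: 0.120        # S/cm^2
    reversal: 50.0     # mV (fixed, textbook value)
    gates:
      - name: m
        exponent: 3
        kinetics:
          form: alpha_beta
          alpha: {kind: explinear, a: 0.1, b: -40.0, c: 10.0}
          beta: {kind: exp, a: 4.0, b: -65.0, c: -18.0}
      - name: h
        exponent: 1
        kinetics:
          form: alpha_beta
          alpha: {kind: exp, a: 0.07, b: -65.0, c: -20.0}
          beta: {kind: sigmoid, a: 1.0, b: -35.0, c: 10.0}
  - name: Kdr
    gbar: 0.036
    reversal: -77.0
    gates:
      - name: n
        exponent: 4
        kinetics:
          form: alpha_beta
          alpha: {kind: explinear, a: 0.01, b: -55.0, c: 10.0}
          beta: {kind: exp, a: 0.125, b: -65.0, c: -80.0}
  - name: leak
    gbar: 0.0003
    reversal: -54.387
    gates: []
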
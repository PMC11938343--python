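label: Mn_L4
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Mn, kind: metal}
- {name: L4, kind: ligand}
- {name: H, kind: proton}
species:
- coeffs: {L4: 1, H: 6}
  log_beta: 37.62
  sigma: 0.04
- coeffs: {L4: 1, H: 5}
  log_beta: 32.42
  sigma: 0.03
- coeffs: {L4: 1, H: 4}
  log_beta: 26.66
  sigma: 0.05
- coeffs: {L4: 1, H: 3}
  log_beta: 20.7
  sigma: 0.4
- coeffs: {L4: 1, H: 2}
  log_beta: 14.14
  sigma: 0.04
- coeffs: {L4: 1, H: 1}
  log_beta: 7.48
  sigma: 0.05
- coeffs: {Mn: 1, L4: 1, H: 4}
  log_beta: 29.53
  sigma: 0.06
- coeffs: {Mn: 1, L4: 1, H: 2}
  log_beta: 17.72
  sigma: 0.02
- coeffs: {Mn: 1, L4: 1}
  log_beta: 3.99
  sigma: 0.02
- coeffs: {Mn: 1, L4: 1, H: -1}
  log_beta: -5.01
  sigma: 0.06
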
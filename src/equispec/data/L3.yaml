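label: L3
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: L3, kind: ligand}
- {name: H, kind: proton}
species:
- coeffs: {L3: 1, H: 5}
  log_beta: 31.52
  sigma: 0.02
- coeffs: {L3: 1, H: 4}
  log_beta: 25.98
  sigma: 0.02
- coeffs: {L3: 1, H: 3}
  log_beta: 20.27
  sigma: 0.03
- coeffs: {L3: 1, H: 2}
  log_beta: 13.87
  sigma: 0.02
- coeffs: {L3: 1, H: 1}
  log_beta: 7.22
  sigma: 0.03
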
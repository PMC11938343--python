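label: Fe_L5
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Fe, kind: metal}
- {name: L5, kind: ligand}
- {name: H, kind: proton}
species:
- coeffs: {L5: 1, H: 9}
  log_beta: 47.0
  sigma: 0.02
- coeffs: {L5: 1, H: 8}
  log_beta: 44.78
  sigma: 0.02
- coeffs: {L5: 1, H: 7}
  log_beta: 41.79
  sigma: 0.01
- coeffs: {L5: 1, H: 6}
  log_beta: 38.22
  sigma: 0.01
- coeffs: {L5: 1, H: 5}
  log_beta: 34.15
  sigma: 0.01
- coeffs: {L5: 1, H: 4}
  log_beta: 28.39
  sigma: 0.01
- coeffs: {L5: 1, H: 3}
  log_beta: 22.06
  sigma: 0.01
- coeffs: {L5: 1, H: 2}
  log_beta: 15.16
  sigma: 0.01
- coeffs: {L5: 1, H: 1}
  log_beta: 7.98
  sigma: 0.01
- coeffs: {Fe: 1, L5: 1, H: 5}
  log_beta: 37.63
  sigma: 0.06
- coeffs: {Fe: 1, L5: 1, H: 4}
  log_beta: 32.76
  sigma: 0.07
- coeffs: {Fe: 1, L5: 1, H: 3}
  log_beta: 26.9
  sigma: 0.06
- coeffs: {Fe: 1, L5: 1, H: 1}
  log_beta: 13.56
  sigma: 0.06
- coeffs: {Fe: 1, L5: 1}
  log_beta: 6.0
  sigma: 0.07
- coeffs: {Fe: 1, L5: 1, H: -1}
  log_beta: -1.86
  sigma: 0.07
- coeffs: {Fe: 1, L5: 1, H: -2}
  log_beta: -10.22
  sigma: 0.06
- coeffs: {Fe: 1, L5: 1, H: -4}
  log_beta: -28.83
  sigma: 0.06
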
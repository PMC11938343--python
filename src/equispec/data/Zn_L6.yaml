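label: Zn_L6
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Zn, kind: metal}
- {name: L6, kind: ligand}
- {name: H, kind: proton}
species:
- coeffs: {L6: 1, H: 9}
  log_beta: 49.22
  sigma: 0.03
- coeffs: {L6: 1, H: 8}
  log_beta: 46.25
  sigma: 0.03
- coeffs: {L6: 1, H: 7}
  log_beta: 42.51
  sigma: 0.03
- coeffs: {L6: 1, H: 6}
  log_beta: 38.43
  sigma: 0.03
- coeffs: {L6: 1, H: 5}
  log_beta: 33.76
  sigma: 0.03
- coeffs: {L6: 1, H: 4}
  log_beta: 27.04
  sigma: 0.03
- coeffs: {L6: 1, H: 3}
  log_beta: 21.61
  sigma: 0.04
- coeffs: {L6: 1, H: 2}
  log_beta: 14.86
  sigma: 0.02
- coeffs: {L6: 1, H: 1}
  log_beta: 7.74
  sigma: 0.03
- coeffs: {Zn: 1, L6: 1, H: 2}
  log_beta: 21.03
  sigma: 0.01
- coeffs: {Zn: 1, L6: 1, H: 1}
  log_beta: 14.62
  sigma: 0.03
- coeffs: {Zn: 1, L6: 1}
  log_beta: 7.58
  sigma: 0.03
- coeffs: {Zn: 1, L6: 1, H: -1}
  log_beta: -1.06
  sigma: 0.05
- coeffs: {Zn: 1, L6: 1, H: -2}
  log_beta: -10.63
  sigma: 0.05
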
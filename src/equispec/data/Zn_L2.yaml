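label: Zn_L2
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Zn, kind: metal}
- {name: L2, kind: ligand}
- {name: H, kind: proton}
species:
- coeffs: {L2: 1, H: 9}
  log_beta: 53.93
  sigma: 0.02
- coeffs: {L2: 1, H: 8}
  log_beta: 49.32
  sigma: 0.03
- coeffs: {L2: 1, H: 7}
  log_beta: 44.39
  sigma: 0.04
- coeffs: {L2: 1, H: 6}
  log_beta: 38.93
  sigma: 0.06
- coeffs: {L2: 1, H: 5}
  log_beta: 33.35
  sigma: 0.06
- coeffs: {L2: 1, H: 4}
  log_beta: 27.36
  sigma: 0.06
- coeffs: {L2: 1, H: 3}
  log_beta: 21.09
  sigma: 0.05
- coeffs: {L2: 1, H: 2}
  log_beta: 14.53
  sigma: 0.02
- coeffs: {L2: 1, H: 1}
  log_beta: 7.42
  sigma: 0.03
- coeffs: {Zn: 1, L2: 1, H: 6}
  log_beta: 43.51
  sigma: 0.04
- coeffs: {Zn: 1, L2: 1, H: 4}
  log_beta: 33.54
  sigma: 0.02
- coeffs: {Zn: 1, L2: 1, H: 2}
  log_beta: 22.61
  sigma: 0.02
- coeffs: {Zn: 1, L2: 1}
  log_beta: 9.99
  sigma: 0.03
- coeffs: {Zn: 1, L2: 1, H: -1}
  log_beta: 2.4
  sigma: 0.05
- coeffs: {Zn: 1, L2: 1, H: -2}
  log_beta: -6.32
  sigma: 0.06
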
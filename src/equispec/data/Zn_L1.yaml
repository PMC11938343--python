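label: Zn_L1
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Zn, kind: metal}
- {name: L1, kind: ligand}
- {name: H, kind: proton}
species:
- coeffs: {L1: 1, H: 6}
  log_beta: 36.98
  sigma: 0.02
- coeffs: {L1: 1, H: 5}
  log_beta: 32.03
  sigma: 0.02
- coeffs: {L1: 1, H: 4}
  log_beta: 26.41
  sigma: 0.03
- coeffs: {L1: 1, H: 3}
  log_beta: 20.54
  sigma: 0.03
- coeffs: {L1: 1, H: 2}
  log_beta: 14.11
  sigma: 0.02
- coeffs: {L1: 1, H: 1}
  log_beta: 7.39
  sigma: 0.03
- coeffs: {Zn: 1, L1: 1, H: 2}
  log_beta: 19.63
  sigma: 0.06
- coeffs: {Zn: 1, L1: 1, H: 1}
  log_beta: 14.26
  sigma: 0.03
- coeffs: {Zn: 1, L1: 1}
  log_beta: 7.66
  sigma: 0.05
- coeffs: {Zn: 1, L1: 1, H: -1}
  log_beta: -1.32
  sigma: 0.08
- coeffs: {Zn: 1, L1: 1, H: -2}
  log_beta: -11.24
  sigma: 0.07
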
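label: Fe_L6
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Fe, kind: metal}
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
- coeffs: {Fe: 1, L6: 1, H: 4}
  log_beta: 31.6
  sigma: 0.09
- coeffs: {Fe: 1, L6: 1, H: 3}
  log_beta: 25.76
  sigma: 0.05
- coeffs: {Fe: 1, L6: 1, H: 1}
  log_beta: 12.35
  sigma: 0.06
- coeffs: {Fe: 1, L6: 1}
  log_beta: 4.65
  sigma: 0.06
- coeffs: {Fe: 1, L6: 1, H: -1}
  log_beta: -3.06
  sigma: 0.06
- coeffs: {Fe: 1, L6: 1, H: -2}
  log_beta: -11.16
  sigma: 0.04
- coeffs: {Fe: 1, L6: 1, H: -4}
  log_beta: -29.89
  sigma: 0.04
notes: ['log beta[FeL] printed with a decimal comma (''4,65''); stored as 4.65.', printed conditional
    Kd at pH 7.0 (1.88e-5) is not derivable from the printed constants (binding-polynomial recomputation
    gives ~5.3e-5).]
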
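label: L6
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
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
notes: ['printed stepwise pKa values 5.82 and 6.33 (steps H5L->H4L and H4L->H3L) are not derivable from
    the printed log beta column (33.76-27.04 = 6.72, 27.04-21.61 = 5.43); the printed pKa ladder is consistent
    with log beta(H4L) = 27.94 instead of 27.04. The beta values are stored as printed.']
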
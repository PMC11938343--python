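label: Fe_L1
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Fe, kind: metal}
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
- coeffs: {Fe: 1, L1: 1, H: 4}
  log_beta: 29.4
  sigma: 0.05
- coeffs: {Fe: 1, L1: 1, H: 2}
  log_beta: 17.9
  sigma: 0.02
- coeffs: {Fe: 1, L1: 1}
  log_beta: 4.61
  sigma: 0.01
- coeffs: {Fe: 1, L1: 1, H: -1}
  log_beta: -12.36
  sigma: 0.02
notes: ['printed log beta[FeLH-1] = -12.36 is inconsistent with the printed pKa ladder (pKa 7.95/8.68
    from FeL = 4.61 imply -3.34/-12.02); stored as printed.']
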
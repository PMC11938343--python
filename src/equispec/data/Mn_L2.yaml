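label: Mn_L2
temperature_K: 298.0
ionic_strength_M: 0.1
pKw: 13.78
components:
- {name: Mn, kind: metal}
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
- coeffs: {Mn: 1, L2: 1, H: 6}
  log_beta: 42.7
  sigma: 0.03
- coeffs: {Mn: 1, L2: 1, H: 4}
  log_beta: 31.64
  sigma: 0.02
- coeffs: {Mn: 1, L2: 1, H: 2}
  log_beta: 19.7
  sigma: 0.02
- coeffs: {Mn: 1, L2: 1, H: 1}
  log_beta: 11.97
  sigma: 0.04
- coeffs: {Mn: 1, L2: 1}
  log_beta: 4.71
  sigma: 0.03
- coeffs: {Mn: 1, L2: 1, H: -1}
  log_beta: -4.88
  sigma: 0.04
- coeffs: {Mn: 1, L2: 1, H: -3}
  log_beta: -25.3
  sigma: 0.03
notes: ['printed pKa[MnHL] = 7.10 is not derivable from the printed constants (19.70 - 11.97 = 7.73);
    beta values stored as printed.', printed conditional Kd at pH 7.0 (3.07e-5) is not derivable from
    the printed constants (binding-polynomial recomputation gives ~1.3e-5).]
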
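# Methods

## Model

The unit of analysis is an equilibrium model: components (metal ion M,
fully deprotonated ligand L, proton H) and a list of species M_pL_qH_r, each
with an overall formation constant on the molar concentration scale,

    β_pqr = [M_pL_qH_r] / ([M]^p [L]^q [H]^r).

Negative proton coefficients encode hydroxo or extra-deprotonated forms
(MLH₋₁ ≡ ML(OH) up to K_w). Free components are implicit species with
log β = 0. Concentration constants are meaningful because the ionic medium
is fixed (0.1 M NaClO₄, 298 K); no activity-coefficient or ionic-strength
correction is attempted, and charge balance is never enforced — the model is
fully specified by β values and analytical totals. Polynuclear
stoichiometries (p > 1) are accepted by the data model but none are shipped:
the packaged tables contain mononuclear 1:1 species only.

Water autoprotolysis defaults to pK_w = 13.78 (the standard value for this
medium and temperature) and is overridable per model file. Metal hydrolysis
constants are user-supplied numbers (species (1,0,−k)); none are shipped,
and they are excluded by default from conditional-Kd and competition
computations (`include_hydrolysis` turns them on), because the published
pH 7 dissociation constants are reproduced well without them.

## Packaged constant tables

`src/equispec/data/*.yaml` transcribe the published log β values for the six
peptides (overall protonation constants H_nL … HL) and the eighteen 1:1
metal systems, digit for digit, with the parenthetical last-digit standard
deviations stored as numeric sigmas (`17.43(4)` → σ = 0.04). A SHA-256 over
the files is frozen in `equispec.synthetic.FIXTURE_SHA256` to guard the
transcription. Four internal inconsistencies of the printed tables are
carried as fixture annotations rather than silently corrected:

- L6: printed stepwise pKa 5.82/6.33 disagree with the printed β column
  (which gives 6.72/5.43); the printed pKa ladder telescopes to 49.22 and is
  consistent with log β(H₄L) = 27.94 rather than the printed 27.04.
- Mn/L2: printed pKa[MnHL] = 7.10 vs 19.70 − 11.97 = 7.73 from the β values.
- Fe/L1: printed log β[FeLH₋₁] = −12.36 is inconsistent with the printed pKa
  ladder (7.95/8.68 imply −3.34/−12.02). Stored as printed; the species is
  negligible below pH ~8 either way.
- Three printed pH-7 dissociation constants (Mn/L2, Zn/L3, Fe/L6) deviate by
  0.37–0.53 log₁₀ from any recomputation with the printed β values and are
  treated as non-derivable. Zn/L6 recomputes 0.12 log₁₀ off — slightly more
  than β-rounding explains — and is checked only loosely. The remaining
  fourteen systems reproduce within 0.10 log₁₀, the residual offset being
  consistent with the 2-decimal rounding of the printed constants.

## Speciation solver

At fixed pH the proton is a known constant folded into effective constants
(log β′ = log β − r·pH) and the remaining mass balances

    T_j = x_j + Σ_s ν_js c_s,   c_s = 10^{log β′_s} Π_k x_k^{ν_ks}

are solved by Newton iteration in y = ln x. The Jacobian
J = diag(x) + νᵀ diag(c) ν is symmetric positive definite for well-posed
problems, which keeps the iteration stable for constants spanning fifty
orders of magnitude. Numerical choices, fixed for determinism: initial guess
x = T (floor 10⁻¹⁰), step capped at |Δln x| ≤ 50, step halving until the
scaled residual norm decreases (≤ 40 halvings), iteration cap 200,
convergence at scaled residual < 10⁻¹² (hard failure above 10⁻⁹). Residuals
are scaled by max(|T_j|, 10⁻¹⁰). Components with zero total are excluded
(free concentration reported as 0, their species dropped). Grid scans
warm-start from the previous point but the solution is pointwise, so results
are grid-independent.

In titration simulations the proton is an unknown with the water term:
the proton balance reads T_H = h − K_w/h + Σ_s r_s c_s, its Jacobian
diagonal gains h + K_w/h, and T_H may be negative (excess strong base).

## Conditional dissociation constant

Kd(pH) is defined as the free-metal concentration at half-saturation of the
ligand. Because all shipped complexes are 1:1, this is algebraically the
ratio of binding polynomials

    Kd = Q_L(h) / Q_M(h),  Q_L = 1 + Σ_r β_{01r} h^r,  Q_M = Σ_r β_{11r} h^r,

optionally multiplied by the metal hydrolysis side-reaction coefficient
α_M(OH) = 1 + Σ β_{10r} h^r. The identity "half-bound ⇔ K′·[M] = 1" makes
the half-saturation point independent of the ligand total, so the analytic
route is cross-checked in the tests against an independent numerical oracle:
bisection over the total metal until Σ[MH_rL] = T_L/2 (T_L = 10⁻⁷ M, where
1:1 binding dominates), using the full mass-balance solver. The two routes
agree to better than 10⁻⁶ relative for all 18 systems at pH 5, 7 and 9.

## Titration simulation, Gran endpoint, calibration

The forward model dilutes initial totals by V0/(V0+V) and adds
−c_t·V/(V0+V) to the proton total (base titrant positive). The electrode
convention is E = E0 + s·log₁₀[H⁺] with s ≈ +59.16 mV/decade at 298 K —
written against hydrogen-ion *concentration*, matching calibration practice
in constant-ionic-strength work; the sign convention is used consistently
everywhere. Ligands are delivered fully protonated, so a scenario's initial
proton total is the strong-acid concentration plus n_max protons per ligand;
this referencing is explicit in every generated protocol. No carbonate,
junction-potential, drift or temperature effects are modelled.

Gran endpoint: F = (V0+V)·[H⁺] (acid branch) or (V0+V)·K_w/[H⁺] (base
branch); a straight line is fitted over the points whose F lies within
20–80 % of the branch maximum (standard practice, overridable) and the
volume-axis intercept is returned with the standard error propagated from
the fit covariance. The function must be monotone over the window.

Calibration: for a strong-acid protocol, [H⁺] follows in closed form from
C_H = h − K_w/h; E is regressed on log₁₀[H⁺] excluding points within a
configurable volume buffer (default 0.02 mL) of the equivalence point, where
the balance is ill-conditioned. Slopes outside 50–62 mV/decade in magnitude
are rejected as non-Nernstian.

## Refinement

Parameters are log β values (plus optional ligand-purity scale factors on
T_L, mirroring Gran-based standardization practice). Weighted residuals
(obs − sim)/σ_i use σ_i² = σ_E² + (∂E/∂V)²·σ_v², with defaults
σ_E = 0.1 mV (or 0.002 pH) and σ_v = 0.002 mL — the standard scheme for this
instrument class; the curve slope is estimated numerically from the
simulated curve. The minimizer is Gauss–Newton with Levenberg–Marquardt
damping: λ starts at 10⁻³, ×10 on a rejected step, ÷10 on an accepted one;
derivatives are forward differences with step 10⁻⁴ in log β (central
differences behind a flag); convergence when the relative objective decrease
is below 10⁻⁷ twice consecutively. The objective never increases across
accepted steps. Uncertainties are σ_fit²·(JᵀJ)⁻¹ with
σ_fit = √(U/(n − m)); a normal-matrix condition number above 10¹² raises an
error naming the near-degenerate parameter combination. Species whose
maximum formation fraction over the data stays below 0.1 % are frozen and
flagged ill-determined instead of being fitted. Species selection is manual
(refine flags); no automatic model search is performed.

## Synthetic data

The generator emulates the stated experimental design: V0 = 3 mL, 0.5 mM
metal with the ligand in 1.1-fold excess (0.5 mM ligand when no metal is
present), 4 mM strong acid, 0.1 M NaOH titrant, 100 points spanning pH 2–11
(the end volume is chosen so the last point reaches the window top),
electrode truth E0 = 400 mV / 59.16 mV per decade, Gaussian observation
noise σ_pH = 0.003 (or 0.1 mV), independent across points, seeded. It does
not emulate electrode drift, carbonate contamination, autocorrelated noise,
Fe(II) oxidation or alkaline Mn(OH)₂ precipitation — all present in real
experiments — so passing recovery tests demonstrate correctness of the
estimator under the stated noise model, not robustness to real-world
systematics.

Test problem sizes are the package's own choices: recovery tests use
60-point titrations and ten seeds (Mn/L3 for the metal-constant round trip —
its four constants represent the typical refinable set; one seed per ligand
for the pKa round trip, which recovers every stepwise pKa within 0.05).
Noiseless recovery is exact to 10⁻³ (observed: ~10⁻¹⁵).

## Known limitations

- Single-electrode, single-titrant protocols; no emf drift refinement, no
  global multi-metal fits beyond what merged models allow.
- Conditional Kd assumes a 1:1 complex family; polynuclear or bis-complex
  systems would need the numerical half-saturation route instead.
- Printed-table inconsistencies listed above are preserved, not corrected;
  anyone re-deriving the flagged quantities will reproduce the discrepancy.
- Crossover pH values in competition profiles are linear interpolations
  between grid points (first-order accurate in the grid step).
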
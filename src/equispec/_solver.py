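"""Damped Newton solver for component mass balances.

The unknowns are the logarithms of the free component concentrations; the
residual of component j is

    F_j = x_j + sum_s nu_js c_s - T_j,    c_s = 10^logbeta_s * prod_k x_k^nu_ks,

scaled by max(|T_j|, SCALE_FLOOR).  When the proton is among the unknowns the
water term (h - Kw/h) is added to its balance so that negative proton totals
(excess strong base) are handled.  Working in log space keeps every free
concentration positive and makes the Newton matrix

    J_jk = x_j delta_jk + sum_s nu_js nu_ks c_s   (+ h + Kw/h on the proton diagonal)

symmetric positive definite for well-posed problems, which is what makes the
iteration robust for formation constants spanning 50 orders of magnitude.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConvergenceError

LN10 = float(np.log(10.0))

#: Residual scale floor: totals below this magnitude are scaled absolutely.
SCALE_FLOOR = 1e-10

#: Convergence tolerance on the scaled residual infinity norm.
TOL = 1e-12

#: Acceptable fallback tolerance: the contract guarantees < 1e-9.
TOL_ACCEPT = 1e-9

MAX_ITER = 200
MAX_HALVINGS = 40
STEP_CAP = 50.0  # cap on |delta ln x| per Newton step


def _concentrations(log_beta: np.ndarray, nu: np.ndarray, y: np.ndarray) -> np.ndarray:
    ln_c = LN10 * log_beta + nu @ y
    return np.exp(np.clip(ln_c, -745.0, 705.0))


def solve_equilibrium(
    log_beta: np.ndarray,
    nu: np.ndarray,
    totals: np.ndarray,
    *,
    proton_index: int | None = None,
    Kw: float = 0.0,
    y0: np.ndarray | None = None,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the mass balances for the free concentrations.

    Parameters
    ----------
    log_beta : (ns,) log10 overall formation constants.
    nu : (ns, nc) signed stoichiometric matrix over the unknown components.
    totals : (nc,) analytical totals; only the proton total may be negative.
    proton_index : column of ``nu`` holding the proton, or None when the
        proton concentration is fixed (its contribution must then already be
        folded into ``log_beta``).
    Kw : water autoprotolysis constant (linear scale); used only when the
        proton is an unknown.
    y0 : optional warm start in ln(free concentration).

    Returns
    -------
    (free, species) : free concentrations (nc,) and species concentrations (ns,).
    """
    log_beta = np.asarray(log_beta, dtype=float)
    nu = np.asarray(nu, dtype=float)
    totals = np.asarray(totals, dtype=float)
    nc = totals.size
    scale = np.maximum(np.abs(totals), SCALE_FLOOR)

    if y0 is not None:
        y = np.array(y0, dtype=float)
    else:
        guess = np.maximum(totals, SCALE_FLOOR)
        if proton_index is not None:
            th = totals[proton_index]
            guess[proton_index] = th if th > SCALE_FLOOR else (
                Kw / max(-th, np.sqrt(Kw)) if Kw > 0 else SCALE_FLOOR
            )
        y = np.log(guess)

    def residual(yv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = np.exp(yv)
        c = _concentrations(log_beta, nu, yv)
        F = x + nu.T @ c - totals
        if proton_index is not None and Kw > 0:
            F[proton_index] -= Kw / x[proton_index]
        return F, x, c

    F, x, c = residual(y)
    norm = float(np.max(np.abs(F / scale)))
    for _ in range(max_iter):
        if norm < tol:
            return x, c
        J = np.diag(x) + nu.T @ (c[:, None] * nu)
        if proton_index is not None and Kw > 0:
            J[proton_index, proton_index] += Kw / x[proton_index]
        try:
            delta = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(J, -F, rcond=None)[0]
        delta = np.clip(delta, -STEP_CAP, STEP_CAP)

        step = 1.0
        best_y, best_norm = None, norm
        for _ in range(MAX_HALVINGS):
            y_try = y + step * delta
            F_try, x_try, c_try = residual(y_try)
            norm_try = float(np.max(np.abs(F_try / scale)))
            if norm_try < best_norm:
                best_y, best_norm = y_try, norm_try
                break
            step *= 0.5
        if best_y is None:
            # No reduction found: take the smallest step anyway; the capped
            # iteration count bounds the damage and keeps the path deterministic.
            best_y = y + step * delta
        y = best_y
        F, x, c = residual(y)
        norm = float(np.max(np.abs(F / scale)))

    if norm < TOL_ACCEPT:
        return x, c
    raise ConvergenceError(
        f"mass-balance iteration did not converge in {max_iter} steps "
        f"(scaled residual {norm:.3e})",
        residual=norm,
    )
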
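"""Refinement of formation constants from titration data.

Weighted nonlinear least squares on the observed titration curves: the
forward model of :mod:`equispec.titration` predicts pH (or emf) at every
titrant volume from trial log beta values, and a Gauss-Newton iteration with
Levenberg-Marquardt damping minimizes

    U = sum_i [(obs_i - sim_i) / sigma_i]^2,
    sigma_i^2 = sigma_E^2 + (dE/dV)_i^2 * sigma_v^2,

the classic weighting for this instrument class (the curve-slope term
inflates the uncertainty of points on steep equivalence jumps, where a tiny
volume error moves the reading a long way).  Standard deviations on the
refined constants come from the scaled inverse normal-equations matrix and
are reported in the ``value(last-digit sigma)`` convention.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ModelError, RefinementError
from .model import EquilibriumModel, format_value_sigma
from .titration import ElectrodeParams, TitrationDataset, TitrationProtocol, simulate_titration

#: Default observation sigma by dataset kind.
DEFAULT_SIGMA_OBS = {"emf_mV": 0.1, "pH": 0.002}
DEFAULT_SIGMA_V = 0.002  # mL

#: Refined species whose maximum formation fraction stays below this are
#: frozen and flagged ill-determined instead of being fitted.
MIN_FORMATION_FRACTION = 1e-3


@dataclass
class RefinementSpec:
    """Everything a refinement needs: model, flags, data, weights, controls."""

    model: EquilibriumModel
    refine: list[dict[str, int]]  # coefficient maps of the species to refine
    datasets: list[tuple[TitrationDataset, TitrationProtocol, ElectrodeParams | None]]
    sigma_obs: float | None = None  # per-point sigma in dataset units
    sigma_v_mL: float = DEFAULT_SIGMA_V
    max_iter: int = 60
    tol: float = 1e-7
    central_differences: bool = False
    ligand_purity: dict[str, float] = field(default_factory=dict)  # scale on T_L
    refine_purity: list[str] = field(default_factory=list)

    def refined_indices(self) -> list[int]:
        indices = []
        for coeffs in self.refine:
            sp = self.model.find_species(**coeffs)
            indices.append(self.model.species.index(sp))
        return indices

    def validate(self) -> None:
        if not self.refine and not self.refine_purity:
            raise ModelError("refinement spec flags no parameter for refinement")
        for ds, _, electrode in self.datasets:
            if ds.kind == "emf_mV" and electrode is None:
                raise ModelError("emf dataset without electrode parameters")


def _apply_trial(
    spec: RefinementSpec, indices: Sequence[int], trial: np.ndarray
) -> tuple[EquilibriumModel, dict[str, float]]:
    model = copy.deepcopy(spec.model)
    n_beta = len(indices)
    for idx, value in zip(indices, trial[:n_beta]):
        model.species[idx].log_beta = float(value)
    purity = dict(spec.ligand_purity)
    for name, value in zip(spec.refine_purity, trial[n_beta:]):
        purity[name] = float(value)
    return model, purity


def _simulate_dataset(
    model: EquilibriumModel,
    dataset: TitrationDataset,
    protocol: TitrationProtocol,
    electrode: ElectrodeParams | None,
    purity: dict[str, float],
) -> np.ndarray:
    proto = protocol
    if purity:
        scaled = dict(protocol.initial_totals)
        for name, factor in purity.items():
            if name in scaled:
                scaled[name] = scaled[name] * factor
        proto = TitrationProtocol(
            initial_volume_mL=protocol.initial_volume_mL,
            initial_totals=scaled,
            titrant_concentration_M=protocol.titrant_concentration_M,
            volume_points_mL=dataset.volumes_mL,
            temperature_K=protocol.temperature_K,
            ionic_strength_M=protocol.ionic_strength_M,
        )
    else:
        proto = TitrationProtocol(
            initial_volume_mL=protocol.initial_volume_mL,
            initial_totals=dict(protocol.initial_totals),
            titrant_concentration_M=protocol.titrant_concentration_M,
            volume_points_mL=dataset.volumes_mL,
            temperature_K=protocol.temperature_K,
            ionic_strength_M=protocol.ionic_strength_M,
        )
    sim = simulate_titration(
        model, proto, electrode if dataset.kind == "emf_mV" else None
    )
    return sim.values


def _point_sigmas(
    sim_values: np.ndarray, volumes: np.ndarray, sigma_obs: float, sigma_v: float
) -> np.ndarray:
    slope = np.gradient(sim_values, volumes)
    return np.sqrt(sigma_obs**2 + slope**2 * sigma_v**2)


def residuals(spec: RefinementSpec, trial_log_betas: Sequence[float]) -> np.ndarray:
    """Weighted residual vector (obs - sim)/sigma_i at the trial constants.

    ``trial_log_betas`` is ordered as ``spec.refine`` (followed by any
    refined ligand-purity factors).  Deterministic; simulation failures are
    reported with the dataset index and volume attached.
    """
    trial = np.asarray(trial_log_betas, dtype=float)
    if not np.all(np.isfinite(trial)):
        raise ModelError("trial parameter values must be finite")
    indices = spec.refined_indices()
    model, purity = _apply_trial(spec, indices, trial)
    out: list[np.ndarray] = []
    for k, (dataset, protocol, electrode) in enumerate(spec.datasets):
        sigma_obs = (
            spec.sigma_obs
            if spec.sigma_obs is not None
            else DEFAULT_SIGMA_OBS[dataset.kind]
        )
        try:
            sim = _simulate_dataset(model, dataset, protocol, electrode, purity)
        except Exception as exc:
            raise RefinementError(f"simulation failed for dataset #{k}: {exc}") from exc
        sigma = _point_sigmas(sim, dataset.volumes_mL, sigma_obs, spec.sigma_v_mL)
        out.append((dataset.values - sim) / sigma)
    return np.concatenate(out)


@dataclass
class RefinementResult:
    """Refined constants with uncertainties and goodness-of-fit statistics."""

    model: EquilibriumModel  # model updated with the refined constants
    refined: list[dict[str, int]]
    values: np.ndarray
    sd: np.ndarray
    sigma_fit: float
    objective: float
    n_obs: int
    n_params: int
    correlation: np.ndarray
    residuals: np.ndarray
    iterations: list[dict] = field(default_factory=list)
    ill_determined: list[dict[str, int]] = field(default_factory=list)
    purity: dict[str, float] = field(default_factory=dict)
    converged: bool = True


def _max_formation_fractions(
    spec: RefinementSpec, indices: Sequence[int], trial: np.ndarray
) -> np.ndarray:
    """Max over all datasets/points of each refined species' formation fraction."""
    model, purity = _apply_trial(spec, indices, trial)
    proton = model.proton_name
    fractions = np.zeros(len(indices))
    for dataset, protocol, electrode in spec.datasets:
        from .speciation import solve_free_concentrations  # local: avoid cycle

        for v in dataset.volumes_mL[:: max(1, len(dataset) // 25)]:
            totals = protocol.totals_at(v, proton=proton)
            # fixed-pH scan is enough for a formation-extent estimate: solve
            # the full point via the titration path
            from .titration import _solve_full_point

            h, free, _ = _solve_full_point(model, totals)
            pt = solve_free_concentrations(
                model,
                {k: val for k, val in totals.items() if k != proton},
                -np.log10(h),
            )
            for j, idx in enumerate(indices):
                sp = model.species[idx]
                conc = pt.species_conc.get(sp.key, 0.0)
                best = 0.0
                for comp, nu in sp.coefficients.items():
                    if comp == proton or nu <= 0:
                        continue
                    t = totals.get(comp, 0.0)
                    if t > 0:
                        best = max(best, nu * conc / t)
                fractions[j] = max(fractions[j], best)
    return fractions


def refine_formation_constants(spec: RefinementSpec) -> RefinementResult:
    """Levenberg-Marquardt refinement of the flagged log beta values.

    The damping parameter starts at 1e-3, is divided by 10 on an accepted
    step and multiplied by 10 on a rejected one; convergence is declared
    when the relative objective decrease falls below ``spec.tol`` twice in a
    row.  The objective never increases across accepted steps.  Species whose
    maximum formation fraction over the data stays below 0.1 % are frozen and
    flagged ill-determined rather than fitted with spurious precision.
    """
    spec.validate()
    indices = spec.refined_indices()
    theta = np.array(
        [spec.model.species[i].log_beta for i in indices]
        + [spec.ligand_purity.get(name, 1.0) for name in spec.refine_purity],
        dtype=float,
    )

    refined_coeffs = list(spec.refine)
    ill_determined: list[dict[str, int]] = []
    if indices:
        formation = _max_formation_fractions(spec, indices, theta)
        keep = formation >= MIN_FORMATION_FRACTION
        if not np.all(keep):
            ill_determined = [c for c, k in zip(refined_coeffs, keep) if not k]
            refined_coeffs = [c for c, k in zip(refined_coeffs, keep) if k]
            spec = copy.copy(spec)
            spec.refine = refined_coeffs
            indices = spec.refined_indices()
            theta = np.concatenate(
                [
                    theta[: len(keep)][keep],
                    theta[len(keep) :],
                ]
            )
    if theta.size == 0:
        raise RefinementError(
            "every flagged species is ill-determined (formation fraction < 0.1 %)"
        )

    step = 1e-4

    def jacobian(theta0: np.ndarray, r0: np.ndarray) -> np.ndarray:
        J = np.empty((r0.size, theta0.size))
        for j in range(theta0.size):
            tp = theta0.copy()
            tp[j] += step
            rp = residuals(spec, tp)
            if spec.central_differences:
                tm = theta0.copy()
                tm[j] -= step
                rm = residuals(spec, tm)
                J[:, j] = (rp - rm) / (2 * step)
            else:
                J[:, j] = (rp - r0) / step
        return J

    r = residuals(spec, theta)
    objective = float(r @ r)
    lam = 1e-3
    log: list[dict] = []
    slow_count = 0
    converged = False
    J = jacobian(theta, r)
    for it in range(spec.max_iter):
        A = J.T @ J
        g = J.T @ r
        D = np.diag(np.maximum(np.diag(A), 1e-12))
        accepted = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(A + lam * D, -g)
            except np.linalg.LinAlgError as exc:
                raise RefinementError(f"singular normal matrix: {exc}") from exc
            theta_try = theta + delta
            try:
                r_try = residuals(spec, theta_try)
                obj_try = float(r_try @ r_try)
            except RefinementError:
                obj_try = np.inf
            if obj_try < objective:
                rel = (objective - obj_try) / max(objective, 1e-300)
                theta, r = theta_try, r_try
                objective = obj_try
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                log.append(
                    {"iter": it, "lambda": lam, "objective": objective, "accepted": True}
                )
                slow_count = slow_count + 1 if rel < spec.tol else 0
                break
            lam = min(lam * 10.0, 1e12)
            log.append(
                {"iter": it, "lambda": lam, "objective": obj_try, "accepted": False}
            )
        if accepted:
            J = jacobian(theta, r)
            if slow_count >= 2:
                converged = True
                break
        else:
            # no usable step at any damping: treat the current point as optimal
            converged = True
            break
    if not converged:
        raise RefinementError(
            f"no convergence within {spec.max_iter} iterations "
            f"(objective {objective:.6g}); iteration log attached",
        )

    n, m = r.size, theta.size
    dof = max(n - m, 1)
    sigma_fit = float(np.sqrt(objective / dof))
    A = J.T @ J
    cond = np.linalg.cond(A)
    if cond > 1e12:
        w, V = np.linalg.eigh(A)
        worst = V[:, 0]
        names = [str(c) for c in refined_coeffs] + [
            f"purity:{p}" for p in spec.refine_purity
        ]
        combo = " + ".join(
            f"{c:+.2f}*{nme}" for c, nme in zip(worst, names) if abs(c) > 0.1
        )
        raise RefinementError(
            f"ill-conditioned normal matrix (cond {cond:.2e}); "
            f"near-degenerate combination: {combo}"
        )
    cov = sigma_fit**2 * np.linalg.inv(A)
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom == 0, 1.0, denom), 0.0)

    n_beta = len(indices)
    model, purity = _apply_trial(spec, indices, theta)
    return RefinementResult(
        model=model,
        refined=refined_coeffs,
        values=theta[:n_beta].copy(),
        sd=sd[:n_beta].copy(),
        sigma_fit=sigma_fit,
        objective=objective,
        n_obs=n,
        n_params=m,
        correlation=corr,
        residuals=r,
        iterations=log,
        ill_determined=ill_determined,
        purity={
            name: float(val) for name, val in zip(spec.refine_purity, theta[n_beta:])
        },
    )


def fit_statistics(result: RefinementResult) -> dict:
    """Summary record: n, m, sigma_fit and the formatted parameter table."""
    table = []
    for coeffs, value, sd in zip(result.refined, result.values, result.sd):
        sp = result.model.find_species(**coeffs)
        table.append(
            {
                "species": result.model.species_name(sp),
                "coefficients": dict(coeffs),
                "log_beta": float(value),
                "sd": float(sd),
                "formatted": format_value_sigma(float(value), float(sd)),
            }
        )
    return {
        "n": result.n_obs,
        "m": result.n_params,
        "sigma_fit": result.sigma_fit,
        "objective": result.objective,
        "parameters": table,
        "ill_determined": result.ill_determined,
    }
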
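"""Fixed-pH speciation, conditional dissociation constants and ligand competition.

All computations here take the free proton concentration as a known constant
(h = 10^-pH) and solve the remaining component mass balances; this matches
how species-distribution diagrams and pH-conditional constants are defined.
Charge balance is never enforced — the model is fully specified by the
formation constants and the analytical totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._solver import LN10, solve_equilibrium
from .exceptions import ConvergenceError, ModelError
from .model import (
    BindingPolynomial,
    Component,
    EquilibriumModel,
    FormationSpecies,
    binding_polynomial,
)

SpeciesKey = tuple[tuple[str, int], ...]


@dataclass
class SpeciationPoint:
    """Converged equilibrium state at one pH."""

    pH: float
    free: dict[str, float]  # free concentrations, incl. the proton
    species_conc: dict[SpeciesKey, float]
    totals: dict[str, float]
    fractions: dict[SpeciesKey | str, float] | None = None
    reference: str | None = None

    def fractions_of(self, reference: str) -> dict[SpeciesKey | str, float]:
        """Species fractions of the reference component's total.

        Includes the free component under the key ``"free"``; the fractions
        sum to 1 by mass balance.
        """
        total = self.totals.get(reference, 0.0)
        if total <= 0:
            return {"free": 1.0}
        out: dict[SpeciesKey | str, float] = {}
        for key, conc in self.species_conc.items():
            nu = dict(key).get(reference, 0)
            if nu > 0:
                out[key] = nu * conc / total
        out["free"] = self.free.get(reference, 0.0) / total
        return out


def _prepare(model: EquilibriumModel, totals: Mapping[str, float]):
    """Split components into active unknowns and excluded (zero-total) ones."""
    proton = model.proton_name
    active: list[str] = []
    excluded: list[str] = []
    for comp in model.components:
        if comp.name == proton:
            continue
        t = float(totals.get(comp.name, 0.0))
        if t < 0:
            raise ModelError(
                f"total for {comp.name!r} must be >= 0 (got {t}); only the "
                "proton total may be negative"
            )
        (active if t > 0 else excluded).append(comp.name)
    species = [
        sp
        for sp in model.species
        if not any(sp.coeff(name) for name in excluded)
    ]
    return proton, active, excluded, species


def solve_free_concentrations(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    pH: float,
    *,
    reference: str | None = None,
    warm_start: np.ndarray | None = None,
) -> SpeciationPoint:
    """Solve every component mass balance at fixed pH.

    Components with zero analytical total are excluded (their free
    concentration is reported as 0 and species containing them are dropped).
    Deterministic: a fixed starting heuristic and a fixed damping schedule.
    """
    if not (0.0 <= pH <= 14.0):
        raise ModelError(f"pH {pH} outside [0, 14]")
    h = 10.0 ** (-pH)
    proton, active, excluded, species = _prepare(model, totals)

    free: dict[str, float] = {proton: h}
    species_conc: dict[SpeciesKey, float] = {}
    if active:
        nu = np.array(
            [[sp.coeff(name) for name in active] for sp in species], dtype=float
        ).reshape(len(species), len(active))
        # fold the fixed proton into the effective constants
        log_beta = np.array(
            [sp.log_beta - sp.coeff(proton) * pH for sp in species], dtype=float
        )
        tvec = np.array([totals[name] for name in active], dtype=float)
        x, c = solve_equilibrium(log_beta, nu, tvec, y0=warm_start)
        free.update(dict(zip(active, x.tolist())))
        species_conc = {sp.key: float(ci) for sp, ci in zip(species, c)}
    for name in excluded:
        free[name] = 0.0

    point = SpeciationPoint(
        pH=pH,
        free=free,
        species_conc=species_conc,
        totals={k: float(v) for k, v in totals.items()},
    )
    if reference is not None:
        point.reference = reference
        point.fractions = point.fractions_of(reference)
    return point


def speciation_table(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    ph_grid: Sequence[float],
    reference: str,
) -> list[SpeciationPoint]:
    """One converged :class:`SpeciationPoint` per grid value.

    Fractions are expressed against ``reference``.  The grid must be strictly
    increasing; each point is warm-started from the previous one, but the
    solution at a given pH is pointwise (grid-independent).
    """
    grid = list(ph_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ModelError("pH grid must be strictly increasing")
    points: list[SpeciationPoint] = []
    proton, active, _, _ = _prepare(model, totals)
    warm = None
    for ph in grid:
        try:
            pt = solve_free_concentrations(
                model, totals, ph, reference=reference, warm_start=warm
            )
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"speciation failed at pH {ph:.3f}: {exc}", residual=exc.residual
            ) from exc
        if active:
            warm = np.log(
                np.maximum([pt.free[name] for name in active], 1e-300)
            )
        points.append(pt)
    return points


def speciation_dataframe(
    points: Sequence[SpeciationPoint], model: EquilibriumModel
) -> pd.DataFrame:
    """Tabulate a speciation scan with the CSV column layout.

    Columns: ``pH``, ``free.<component>``, ``conc.<p.q.r>``, ``frac.<p.q.r>``
    (the p.q.r labels collapse metal/ligand/proton coefficients and therefore
    presume a single-metal, single-ligand model).
    """
    key_to_pqr = {sp.key: model.species_pqr(sp) for sp in model.species}
    rows = []
    for pt in points:
        row: dict[str, float] = {"pH": pt.pH}
        for name, value in pt.free.items():
            row[f"free.{name}"] = value
        for key, conc in pt.species_conc.items():
            p, q, r = key_to_pqr[key]
            row[f"conc.{p}.{q}.{r}"] = conc
        if pt.fractions is not None:
            for key, frac in pt.fractions.items():
                if key == "free":
                    row["frac.free"] = frac
                else:
                    p, q, r = key_to_pqr[key]
                    row[f"frac.{p}.{q}.{r}"] = frac
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


# ---------------------------------------------------------------------------
# Conditional dissociation constants
# ---------------------------------------------------------------------------


def hydrolysis_alpha(model: EquilibriumModel, h: float, metal: str | None = None) -> float:
    """Metal side-reaction coefficient alpha_M(OH) = 1 + sum_r beta_(1,0,r) h^r.

    Built from the hydrolysis species (metal with no ligand) configured on the
    model; equals 1 when none are configured.
    """
    metals = model.metal_names
    if metal is None:
        if len(metals) != 1:
            raise ModelError("specify the metal for the hydrolysis coefficient")
        metal = metals[0]
    proton = model.proton_name
    alpha = 1.0
    for sp in model.species:
        others = {
            k: v for k, v in sp.coefficients.items() if v != 0 and k not in (metal, proton)
        }
        if sp.coeff(metal) == 1 and not others:
            alpha += 10.0**sp.log_beta * h ** sp.coeff(proton)
    return alpha


def conditional_kd(
    model: EquilibriumModel,
    pH: float,
    *,
    include_hydrolysis: bool = False,
    metal: str | None = None,
    ligand: str | None = None,
) -> float:
    """pH-conditional dissociation constant (mol dm^-3).

    The free-metal concentration at half-saturation of the ligand, absorbing
    every protonation state of ligand and complex:

        Kd(pH) = Q_L(h) / Q_M(h),
        Q_L(h) = 1 + sum_r beta_(0,1,r) h^r,   Q_M(h) = sum_r beta_(1,1,r) h^r,

    with h = 10^-pH.  When ``include_hydrolysis`` is set, Q_L is further
    multiplied by the metal hydrolysis side-reaction coefficient built from
    the model's configured hydrolysis constants.
    """
    h = 10.0 ** (-pH)
    q_ligand = binding_polynomial(model, "ligand", ligand=ligand).evaluate(h)
    q_metal = binding_polynomial(
        model, "metal_complex", metal=metal, ligand=ligand
    ).evaluate(h)
    if include_hydrolysis:
        q_ligand *= hydrolysis_alpha(model, h, metal=metal)
    return q_ligand / q_metal


def kd_half_bound_oracle(
    model: EquilibriumModel,
    pH: float,
    T_L: float = 1e-7,
    *,
    metal: str | None = None,
    ligand: str | None = None,
) -> float:
    """Independent numerical route to the conditional Kd.

    Bisects over the total metal concentration until the summed 1:1 complex
    concentration equals T_L/2 (half-saturation), using the full mass-balance
    solver, and returns the free metal concentration at that point.  T_L must
    be small enough that 1:1 binding dominates (<= 1e-6 recommended).
    Intended for testing against :func:`conditional_kd`.
    """
    metals = model.metal_names
    ligands = model.ligand_names
    met = metal or (metals[0] if len(metals) == 1 else None)
    lig = ligand or (ligands[0] if len(ligands) == 1 else None)
    if met is None or lig is None:
        raise ModelError("specify metal and ligand for the half-bound oracle")

    def bound_minus_half(T_M: float) -> float:
        pt = solve_free_concentrations(model, {met: T_M, lig: T_L}, pH)
        bound = sum(
            conc
            for key, conc in pt.species_conc.items()
            if dict(key).get(met, 0) >= 1 and dict(key).get(lig, 0) >= 1
        )
        return bound - T_L / 2.0

    lo = T_L * 1e-9
    hi = T_L
    f_hi = bound_minus_half(hi)
    for _ in range(60):
        if f_hi > 0:
            break
        hi *= 10.0
        f_hi = bound_minus_half(hi)
    else:
        raise ModelError("half-bound oracle: failed to bracket half-saturation")
    if bound_minus_half(lo) > 0:
        raise ModelError("half-bound oracle: lower bracket already half-bound")
    T_M_star = brentq(bound_minus_half, lo, hi, xtol=1e-300, rtol=8.9e-16)
    pt = solve_free_concentrations(model, {met: T_M_star, lig: T_L}, pH)
    return pt.free[met]


# ---------------------------------------------------------------------------
# Ligand competition
# ---------------------------------------------------------------------------


@dataclass
class CompetitionProfile:
    """Per-ligand bound-metal fraction curves over a pH grid."""

    ph: np.ndarray
    bound: dict[str, np.ndarray]  # ligand name -> bound-metal fraction
    unbound: np.ndarray  # free (plus hydroxo) metal fraction
    crossovers: list[tuple[float, str, str]] = field(default_factory=list)
    metal: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        data = {"pH": self.ph}
        for name, curve in self.bound.items():
            data[f"bound.{name}"] = curve
        data["unbound"] = self.unbound
        return pd.DataFrame(data)


def merge_models(
    models: Sequence[EquilibriumModel],
    *,
    include_hydrolysis: bool = False,
    label: str = "merged",
) -> EquilibriumModel:
    """Union of single-metal models sharing the same metal and proton.

    Ligand names must be distinct across models; metal hydrolysis species are
    dropped unless ``include_hydrolysis`` is set (duplicate hydrolysis entries
    must agree on log beta).
    """
    if not models:
        raise ModelError("merge_models: empty model list")
    metal_sets = [tuple(m.metal_names) for m in models]
    if any(len(ms) != 1 for ms in metal_sets) or len(set(metal_sets)) != 1:
        raise ModelError("competition models must share exactly one common metal")
    metal = metal_sets[0][0]
    proton = models[0].proton_name
    if any(m.proton_name != proton for m in models):
        raise ModelError("competition models must share the proton component")

    components: list[Component] = [Component(metal, "metal"), Component(proton, "proton")]
    seen_ligands: set[str] = set()
    species: list[FormationSpecies] = []
    seen_keys: dict[SpeciesKey, float] = {}
    for m in models:
        for lig in m.ligand_names:
            if lig in seen_ligands:
                raise ModelError(f"ligand name collision: {lig!r} appears twice")
            seen_ligands.add(lig)
            components.append(Component(lig, "ligand"))
        for sp in m.species:
            is_hydrolysis = sp.coeff(metal) >= 1 and not any(
                sp.coeff(l) for l in m.ligand_names
            )
            if is_hydrolysis and not include_hydrolysis:
                continue
            if sp.key in seen_keys:
                if abs(seen_keys[sp.key] - sp.log_beta) > 1e-12:
                    raise ModelError(
                        f"conflicting log beta for shared species {dict(sp.key)}"
                    )
                continue
            seen_keys[sp.key] = sp.log_beta
            species.append(
                FormationSpecies(dict(sp.coefficients), sp.log_beta, sp.sigma_log_beta)
            )
    first = models[0]
    return EquilibriumModel(
        label=label,
        components=components,
        species=species,
        pKw=first.pKw,
        temperature_K=first.temperature_K,
        ionic_strength_M=first.ionic_strength_M,
    )


def competition_profile(
    models: Sequence[EquilibriumModel],
    concentration: float,
    ph_grid: Sequence[float],
    *,
    include_hydrolysis: bool = False,
) -> CompetitionProfile:
    """Equimolar competition of several ligands for one metal.

    Every total (the metal and each ligand) is set to ``concentration``; the
    merged model is solved at each grid point.  Crossover pH values, where
    the dominant ligand changes, are located by linear interpolation between
    grid points.
    """
    merged = merge_models(models, include_hydrolysis=include_hydrolysis)
    metal = merged.metal_names[0]
    ligands = merged.ligand_names
    totals = {metal: concentration, **{l: concentration for l in ligands}}
    points = speciation_table(merged, totals, ph_grid, reference=metal)

    ph = np.array([pt.pH for pt in points])
    bound = {l: np.zeros(len(points)) for l in ligands}
    unbound = np.zeros(len(points))
    for i, pt in enumerate(points):
        metal_in_species = 0.0
        for key, conc in pt.species_conc.items():
            coeffs = dict(key)
            p = coeffs.get(metal, 0)
            if p < 1:
                continue
            carrier = next((l for l in ligands if coeffs.get(l, 0) >= 1), None)
            if carrier is None:
                unbound[i] += p * conc / concentration  # hydroxo forms count as unbound
            else:
                bound[carrier][i] += p * conc / concentration
            metal_in_species += p * conc
        unbound[i] += pt.free[metal] / concentration

    crossovers: list[tuple[float, str, str]] = []
    stacked = np.vstack([bound[l] for l in ligands])
    dominant = [ligands[j] for j in np.argmax(stacked, axis=0)]
    for i in range(1, len(ph)):
        a, b = dominant[i - 1], dominant[i]
        if a != b:
            diff0 = bound[a][i - 1] - bound[b][i - 1]
            diff1 = bound[a][i] - bound[b][i]
            if diff0 == diff1:
                t = 0.5
            else:
                t = diff0 / (diff0 - diff1)
            crossovers.append((float(ph[i - 1] + t * (ph[i] - ph[i - 1])), a, b))
    return CompetitionProfile(
        ph=ph, bound=bound, unbound=unbound, crossovers=crossovers, metal=metal
    )
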
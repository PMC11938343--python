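"""Equilibrium data model: components, formation species and overall constants.

The unit of analysis is an :class:`EquilibriumModel` — a set of components
(metal ions, fully deprotonated ligands, the proton) together with the list
of species that can form from them.  Each species M_pL_qH_r carries an
overall (cumulative) formation constant on the molar scale,

    beta(M_pL_qH_r) = [M_pL_qH_r] / ([M]^p [L]^q [H]^r),

reported as log10(beta).  A negative proton coefficient r encodes hydroxo
or extra-deprotonated forms (MLH_-1 is equivalent to ML(OH) + H2O up to the
water autoprotolysis constant).  Free components are implicit species with
log beta = 0 and are never listed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import ModelError

VALID_KINDS = ("metal", "ligand", "proton")

#: Water autoprotolysis constant (-log10 Kw) at 298 K, I = 0.1 M inert
#: 1:1 electrolyte; overridable per model.
DEFAULT_PKW = 13.78


@dataclass(frozen=True)
class Component:
    """A chemical building block over which stoichiometries are expressed."""

    name: str
    kind: str  # one of "metal", "ligand", "proton"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ModelError(
                f"component {self.name!r}: kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )


@dataclass
class FormationSpecies:
    """One species with its overall formation constant.

    ``coefficients`` maps component name -> signed stoichiometric coefficient
    (p for the metal, q for the ligand, r for the proton; r < 0 for hydroxo /
    deprotonated forms).  ``sigma_log_beta`` is the standard deviation on
    log beta when known (the parenthetical last-digit uncertainty of the
    source tables).
    """

    coefficients: dict[str, int]
    log_beta: float
    sigma_log_beta: float | None = None
    note: str | None = None

    @property
    def key(self) -> tuple[tuple[str, int], ...]:
        """Canonical hashable identity: sorted (component, coefficient) pairs."""
        return tuple(sorted((k, v) for k, v in self.coefficients.items() if v != 0))

    def coeff(self, name: str) -> int:
        return self.coefficients.get(name, 0)


@dataclass
class EquilibriumModel:
    """Component set + species list + ionic-medium metadata."""

    label: str
    components: list[Component]
    species: list[FormationSpecies]
    pKw: float = DEFAULT_PKW
    temperature_K: float = 298.0
    ionic_strength_M: float = 0.1
    notes: list[str] = field(default_factory=list)

    # -- component bookkeeping -------------------------------------------------

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def names_of_kind(self, kind: str) -> list[str]:
        return [c.name for c in self.components if c.kind == kind]

    @property
    def metal_names(self) -> list[str]:
        return self.names_of_kind("metal")

    @property
    def ligand_names(self) -> list[str]:
        return self.names_of_kind("ligand")

    @property
    def proton_name(self) -> str:
        protons = self.names_of_kind("proton")
        if len(protons) != 1:
            raise ModelError(
                f"model {self.label!r}: expected exactly one proton component, found {protons}"
            )
        return protons[0]

    # -- species lookups -------------------------------------------------------

    def species_pqr(self, sp: FormationSpecies) -> tuple[int, int, int]:
        """Collapse a species to (p, q, r) = (metal, ligand, proton) totals.

        Only meaningful for single-metal / single-ligand models; merged
        competition models should address species by :attr:`FormationSpecies.key`.
        """
        p = sum(sp.coeff(m) for m in self.metal_names)
        q = sum(sp.coeff(l) for l in self.ligand_names)
        r = sp.coeff(self.proton_name)
        return (p, q, r)

    def find_species(self, **coefficients: int) -> FormationSpecies:
        wanted = tuple(sorted((k, v) for k, v in coefficients.items() if v != 0))
        for sp in self.species:
            if sp.key == wanted:
                return sp
        raise ModelError(f"model {self.label!r}: no species with coefficients {coefficients}")

    def species_name(self, sp: FormationSpecies) -> str:
        """Human-readable species name in the MH_nL / MLH_-n convention."""
        metal = "".join(
            m if sp.coeff(m) == 1 else f"{m}{sp.coeff(m)}"
            for m in self.metal_names
            if sp.coeff(m)
        )
        ligand = "".join(
            l if sp.coeff(l) == 1 else f"{l}{sp.coeff(l)}"
            for l in self.ligand_names
            if sp.coeff(l)
        )
        r = sp.coeff(self.proton_name)
        if r > 0:
            h = "H" if r == 1 else f"H{r}"
            return f"{metal}{h}{ligand}" if (metal or ligand) else h
        if r < 0:
            return f"{metal}{ligand}H{r}"
        return f"{metal}{ligand}"


def validate_model(model: EquilibriumModel) -> list[str]:
    """Return a list of human-readable diagnostics; empty for a well-formed model.

    Never raises and never mutates the model.
    """
    diagnostics: list[str] = []
    names = model.component_names
    seen: set[str] = set()
    for name in names:
        if name in seen:
            diagnostics.append(f"duplicate component name {name!r}")
        seen.add(name)

    protons = model.names_of_kind("proton")
    if len(protons) != 1:
        diagnostics.append(
            f"model must declare exactly one proton component, found {len(protons)}"
        )

    if not (12.0 <= model.pKw <= 15.0):
        diagnostics.append(f"pKw {model.pKw} outside the plausible range [12, 15]")

    seen_keys: set[tuple] = set()
    for i, sp in enumerate(model.species):
        label = f"species #{i}"
        nonzero = {k: v for k, v in sp.coefficients.items() if v != 0}
        if not nonzero:
            diagnostics.append(f"{label}: no nonzero stoichiometric coefficient")
            continue
        for comp in nonzero:
            if comp not in names:
                diagnostics.append(
                    f"{label}: references undeclared component {comp!r}"
                )
        if sp.key in seen_keys:
            diagnostics.append(
                f"{label}: duplicate stoichiometry {dict(sp.key)} already declared"
            )
        seen_keys.add(sp.key)
        if len(nonzero) == 1 and next(iter(nonzero.values())) == 1:
            diagnostics.append(
                f"{label}: free component {next(iter(nonzero))!r} must not be listed "
                "as a species (it is implicit with log beta = 0)"
            )
        if sp.sigma_log_beta is not None and sp.sigma_log_beta < 0:
            diagnostics.append(f"{label}: negative sigma_log_beta")
    return diagnostics


def stepwise_pka(ligand_betas: Sequence[float]) -> list[float]:
    """Stepwise acidity constants from overall protonation constants.

    ``ligand_betas`` lists log beta(H_nL) ... log beta(HL), from the highest
    protonation state down.  The k-th stepwise constant is

        pKa_k = log beta(H_kL) - log beta(H_{k-1}L),   log beta(H_0L) = 0,

    and the return value is ordered from the most acidic step (loss of the
    first proton from H_nL) to the least acidic (HL -> L).
    """
    betas = list(ligand_betas)
    if not betas:
        raise ModelError("stepwise_pka: no protonation constants supplied")
    shifted = betas[1:] + [0.0]
    return [b - s for b, s in zip(betas, shifted)]


@dataclass
class BindingPolynomial:
    """Coefficients of a binding polynomial Q(h) = sum_r beta_r h^r.

    ``terms`` maps the proton coefficient r to the linear-scale beta_r.  The
    ligand-side polynomial carries the implicit r = 0, beta = 1 term for the
    free component; the 1:1 metal-complex polynomial does not.
    """

    terms: dict[int, float]

    def evaluate(self, h: float) -> float:
        if h <= 0:
            raise ValueError("binding polynomial requires h > 0")
        return sum(beta * h**r for r, beta in self.terms.items())

    def log10_evaluate(self, h: float) -> float:
        return math.log10(self.evaluate(h))


def binding_polynomial(
    model: EquilibriumModel,
    family: str,
    *,
    metal: str | None = None,
    ligand: str | None = None,
) -> BindingPolynomial:
    """Extract the proton binding polynomial of a species family.

    ``family`` selects either the ligand protonation family {(0,1,r)}
    (``"ligand"``) or the 1:1 metal-complex family {(1,1,r)}
    (``"metal_complex"``).  For models with a single metal/ligand the
    ``metal``/``ligand`` names may be omitted.
    """
    if family not in ("ligand", "metal_complex"):
        raise ModelError(f"unknown species family {family!r}")

    def _pick(names: list[str], given: str | None, what: str) -> str:
        if given is not None:
            if given not in names:
                raise ModelError(f"model {model.label!r} has no {what} {given!r}")
            return given
        if len(names) != 1:
            raise ModelError(
                f"model {model.label!r} has {len(names)} {what}s; specify one explicitly"
            )
        return names[0]

    lig = _pick(model.ligand_names, ligand, "ligand")
    proton = model.proton_name
    terms: dict[int, float] = {}
    if family == "ligand":
        for sp in model.species:
            others = {
                k: v
                for k, v in sp.coefficients.items()
                if v != 0 and k not in (lig, proton)
            }
            if sp.coeff(lig) == 1 and not others:
                terms[sp.coeff(proton)] = 10.0**sp.log_beta
        terms.setdefault(0, 1.0)
    else:
        met = _pick(model.metal_names, metal, "metal")
        for sp in model.species:
            others = {
                k: v
                for k, v in sp.coefficients.items()
                if v != 0 and k not in (met, lig, proton)
            }
            if sp.coeff(met) == 1 and sp.coeff(lig) == 1 and not others:
                terms[sp.coeff(proton)] = 10.0**sp.log_beta
        if not terms:
            raise ModelError(
                f"model {model.label!r}: no 1:1 {met}-{lig} species; "
                "metal-complex binding polynomial is empty"
            )
    return BindingPolynomial(terms=terms)


def parse_value_sigma(text: str) -> tuple[float, float | None]:
    """Parse the ``"17.43(4)"`` table convention into (value, sigma).

    The parenthetical digits are the standard deviation on the last printed
    digits: ``"17.43(4)" -> (17.43, 0.04)``, ``"20.7(4)" -> (20.7, 0.4)``.
    """
    text = text.strip()
    if "(" not in text:
        return float(text), None
    value_part, sigma_part = text.split("(", 1)
    sigma_digits = sigma_part.rstrip(")")
    if "." in value_part:
        decimals = len(value_part.split(".", 1)[1])
    else:
        decimals = 0
    sigma = int(sigma_digits) * 10.0 ** (-decimals)
    return float(value_part), sigma


def format_value_sigma(value: float, sigma: float | None) -> str:
    """Format a refined constant in the ``value(last-digit sigma)`` style.

    ``(17.43, 0.04) -> "17.43(4)"``; ``(7.980, 0.005) -> "7.980(5)"``; a zero
    or missing sigma yields the plain value.
    """
    if sigma is None or sigma == 0:
        return f"{value:g}"
    exponent = math.floor(math.log10(sigma))
    digit = round(sigma / 10.0**exponent)
    if digit == 10:
        exponent += 1
        digit = 1
    decimals = -exponent
    if decimals <= 0:
        return f"{value:.0f}({digit * 10**exponent:d})"
    return f"{value:.{decimals}f}({digit})"
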
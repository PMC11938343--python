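"""Packaged constant-table fixtures and synthetic titration generation.

The fixture files under ``equispec/data`` transcribe the published overall
formation constants for six His-rich model peptides (L1-L6) and their 1:1
complexes with Mn(II), Fe(II) and Zn(II) at 298 K, I = 0.1 M NaClO4, with
the parenthetical last-digit standard deviations.  The synthetic titration
generator emulates the study design those constants were refined from:
0.5 mM ligand, 1:1.1 metal-to-ligand ratio, 4 mM strong acid, 0.1 M inert
electrolyte, carbonate-free 0.1 M NaOH titrant, pH window 2-11, Nernstian
electrode with independent Gaussian measurement noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import ModelError
from .io import model_from_dict
from .model import Component, EquilibriumModel
from .titration import ElectrodeParams, TitrationDataset, TitrationProtocol, simulate_titration
import yaml

LIGAND_LABELS = ("L1", "L2", "L3", "L4", "L5", "L6")
METAL_LABELS = ("Mn", "Fe", "Zn")
FIXTURE_LABELS = LIGAND_LABELS + tuple(
    f"{m}_{l}" for m in METAL_LABELS for l in LIGAND_LABELS
)

#: SHA-256 over the concatenated fixture files (sorted by label); guards the
#: table transcription against accidental edits.
FIXTURE_SHA256 = "d08d1973e88c87a96ff4a8bfd6b6c53250ec4499807d116d213840c212bbf0ec"


def _fixture_bytes(label: str) -> bytes:
    ref = resources.files("equispec").joinpath("data", f"{label}.yaml")
    return ref.read_bytes()


def fixture_path(label: str) -> Path:
    """Filesystem path of a packaged fixture (for CLI/examples)."""
    if label not in FIXTURE_LABELS:
        raise ModelError(f"unknown fixture {label!r}; choose from {FIXTURE_LABELS}")
    with resources.as_file(
        resources.files("equispec").joinpath("data", f"{label}.yaml")
    ) as p:
        return Path(p)


def load_fixture(label: str) -> EquilibriumModel:
    """Load one packaged constant-table model by label (e.g. ``"Mn_L3"``)."""
    if label not in FIXTURE_LABELS:
        raise ModelError(f"unknown fixture {label!r}; choose from {FIXTURE_LABELS}")
    data = yaml.safe_load(_fixture_bytes(label).decode("utf-8"))
    return model_from_dict(data, context=f"fixture {label}")


def paper_fixture_models() -> dict[str, EquilibriumModel]:
    """All 6 ligand-protonation models and 18 metal-ligand models, by label."""
    return {label: load_fixture(label) for label in FIXTURE_LABELS}


def fixture_checksum() -> str:
    digest = hashlib.sha256()
    for label in sorted(FIXTURE_LABELS):
        digest.update(_fixture_bytes(label))
    return digest.hexdigest()


def strong_acid_model(pKw: float = 13.78, label: str = "strong_acid") -> EquilibriumModel:
    """Proton-only model (no species): strong acid vs strong base titrations."""
    return EquilibriumModel(
        label=label,
        components=[Component("H", "proton")],
        species=[],
        pKw=pKw,
    )


# ---------------------------------------------------------------------------
# Titration scenarios
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """One synthetic titration under the study's experimental design.

    Defaults reproduce the stated conditions: V0 = 3 mL, 0.5 mM metal with
    ligand in 1.1-fold excess (0.5 mM ligand when no metal is present), 4 mM
    strong acid, 0.1 M NaOH titrant, 100 points across the pH 2-11 window.
    The proton total is referenced to the fully deprotonated ligand, so the
    initial acid total is the strong-acid concentration plus n_max protons
    per ligand (the ligand is delivered fully protonated, H_nL).
    """

    model_label: str
    v0_mL: float = 3.0
    metal_total_M: float | None = None  # None -> 5e-4 when the model has a metal
    ligand_total_M: float | None = None  # None -> 5.5e-4 (metal) / 5e-4 (ligand only)
    acid_M: float = 4e-3
    titrant_M: float = 0.1
    n_points: int = 100
    ph_min: float = 2.0
    ph_max: float = 11.0
    observed_kind: str = "pH"  # "pH" or "emf_mV"
    electrode_E0_mV: float = 400.0
    electrode_slope_mV: float = 59.16
    sigma_obs: float = 0.003  # pH units (or mV for emf datasets)
    sigma_v_mL: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_obs < 0 or self.sigma_v_mL < 0:
            raise ModelError("noise sigmas must be >= 0")
        if (self.sigma_obs > 0 or self.sigma_v_mL > 0) and self.seed is None:
            raise ModelError("a seed is mandatory for any nonzero noise")

    def electrode(self) -> ElectrodeParams:
        return ElectrodeParams(E0_mV=self.electrode_E0_mV, slope_mV=self.electrode_slope_mV)

    def resolve_totals(self, model: EquilibriumModel) -> dict[str, float]:
        metals = model.metal_names
        ligands = model.ligand_names
        totals: dict[str, float] = {}
        t_l = self.ligand_total_M
        if ligands:
            if t_l is None:
                t_l = 5.5e-4 if metals else 5e-4
            totals[ligands[0]] = t_l
        if metals:
            totals[metals[0]] = 5e-4 if self.metal_total_M is None else self.metal_total_M
        # proton total: strong acid + fully protonated ligand
        n_max = 0
        proton = model.proton_name
        for sp in model.species:
            if sp.coeff(proton) > 0 and not any(sp.coeff(m) for m in metals):
                n_max = max(n_max, sp.coeff(proton))
        totals[proton] = self.acid_M + n_max * totals.get(
            ligands[0] if ligands else "", 0.0
        )
        return totals

    def to_protocol(self, model: EquilibriumModel) -> TitrationProtocol:
        totals = self.resolve_totals(model)
        th0 = totals[model.proton_name]
        oh_end = 10.0 ** (-(model.pKw - self.ph_max))
        v_end = self.v0_mL * (th0 + oh_end) / (self.titrant_M - oh_end)
        volumes = np.linspace(0.0, v_end, self.n_points)
        return TitrationProtocol(
            initial_volume_mL=self.v0_mL,
            initial_totals=totals,
            titrant_concentration_M=self.titrant_M,
            volume_points_mL=volumes,
            temperature_K=model.temperature_K,
            ionic_strength_M=model.ionic_strength_M,
        )


def generate_noisy_titration(
    scenario: Scenario, model: EquilibriumModel | None = None
) -> TitrationDataset:
    """Simulate the scenario and perturb it with independent Gaussian noise.

    Identical scenarios (including the seed) give bit-identical datasets;
    zero sigmas return the clean simulation.  The metadata records the truth
    (electrode parameters, scenario fields, seed).
    """
    if model is None:
        model = load_fixture(scenario.model_label)
    protocol = scenario.to_protocol(model)
    electrode = scenario.electrode() if scenario.observed_kind == "emf_mV" else None
    clean = simulate_titration(model, protocol, electrode)
    values = clean.values.copy()
    volumes = clean.volumes_mL.copy()
    if scenario.sigma_obs > 0 or scenario.sigma_v_mL > 0:
        rng = np.random.default_rng(scenario.seed)
        if scenario.sigma_obs > 0:
            values = values + rng.normal(0.0, scenario.sigma_obs, size=values.size)
        if scenario.sigma_v_mL > 0:
            volumes = volumes + rng.normal(0.0, scenario.sigma_v_mL, size=volumes.size)
            order = np.argsort(volumes, kind="stable")
            volumes, values = volumes[order], values[order]
    sigma = np.full_like(values, scenario.sigma_obs)
    return TitrationDataset(
        volumes_mL=volumes,
        values=values,
        kind=clean.kind,
        sigma=sigma,
        metadata={
            "scenario": {
                "model_label": scenario.model_label,
                "v0_mL": scenario.v0_mL,
                "acid_M": scenario.acid_M,
                "titrant_M": scenario.titrant_M,
                "n_points": scenario.n_points,
                "sigma_obs": scenario.sigma_obs,
                "sigma_v_mL": scenario.sigma_v_mL,
                "seed": scenario.seed,
            },
            "electrode_truth": {
                "E0_mV": scenario.electrode_E0_mV,
                "slope_mV": scenario.electrode_slope_mV,
            },
            "synthetic": True,
        },
    )
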
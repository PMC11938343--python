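import numpy as np
import pytest
from scipy.optimize import brentq

from equispec import (
    Component,
    EquilibriumModel,
    FormationSpecies,
    ModelError,
    binding_polynomial,
    competition_profile,
    conditional_kd,
    hydrolysis_alpha,
    kd_half_bound_oracle,
    merge_models,
    load_fixture,
    solve_free_concentrations,
    speciation_table,
)


def check_mass_balance(model, point, tol=1e-9):
    """Recompute every non-proton total from the solved point."""
    for comp in model.components:
        name = comp.name
        if comp.kind == "proton":
            continue
        total = point.totals.get(name, 0.0)
        recomputed = point.free[name] + sum(
            dict(key).get(name, 0) * conc
            for key, conc in point.species_conc.items()
        )
        assert abs(recomputed - total) / max(abs(total), 1e-15) < tol, name


def test_half_protonation_at_matched_pka(hl_model):
    # beta * h = 1 at pH 7 forces [L] = [HL] = T/2
    pt = solve_free_concentrations(hl_model, {"L": 1e-3}, 7.00)
    assert pt.free["L"] == pytest.approx(5.0e-4, rel=1e-9)
    (conc,) = pt.species_conc.values()
    assert conc == pytest.approx(5.0e-4, rel=1e-9)


def test_unbound_metal_equals_total(hl_model):
    model = EquilibriumModel(
        label="t",
        components=[
            Component("M", "metal"),
            Component("L", "ligand"),
            Component("H", "proton"),
        ],
        species=[FormationSpecies({"L": 1, "H": 1}, 7.0)],
    )
    pt = solve_free_concentrations(model, {"M": 5e-4, "L": 1e-3}, 7.0)
    assert pt.free["M"] == pytest.approx(5e-4, rel=1e-12)


def test_bound_fraction_matches_scalar_bisection_oracle(models):
    """Full Newton solve vs a 1D bisection on the lumped 1:1 binding equation."""
    model = models["Mn_L3"]
    t_m, t_l, ph = 5e-4, 5.5e-4, 7.00
    pt = solve_free_concentrations(model, {"Mn": t_m, "L3": t_l}, ph)
    bound = sum(
        conc for key, conc in pt.species_conc.items() if dict(key).get("Mn", 0) >= 1
    )
    # oracle: conditional formation constant K' = Q_M/Q_L lumps all protonation
    # states; solve m + K' m T_L/(1 + K' m) = T_M for the free metal by bisection
    h = 10.0**-ph
    kcond = binding_polynomial(model, "metal_complex").evaluate(h) / binding_polynomial(
        model, "ligand"
    ).evaluate(h)

    def f(m):
        return m + kcond * m * t_l / (1.0 + kcond * m) - t_m

    m_star = brentq(f, 1e-30, t_m, rtol=8.9e-16)
    bound_oracle = kcond * m_star * t_l / (1.0 + kcond * m_star)
    assert bound / t_m == pytest.approx(bound_oracle / t_m, rel=1e-6)


@pytest.mark.parametrize("label", ["Mn_L1", "Fe_L5", "Zn_L2", "L4"])
@pytest.mark.parametrize("ph", [3.0, 7.0, 10.5])
def test_mass_balance_closure(models, label, ph):
    model = models[label]
    totals = {name: 5e-4 for name in model.metal_names}
    totals.update({name: 5.5e-4 for name in model.ligand_names})
    pt = solve_free_concentrations(model, totals, ph)
    check_mass_balance(model, pt)


def test_fractions_sum_to_one(models):
    model = models["Zn_L5"]
    pts = speciation_table(
        model, {"Zn": 5e-4, "L5": 5.5e-4}, np.arange(2.0, 11.01, 0.5), reference="Zn"
    )
    for pt in pts:
        assert sum(pt.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_mnl1_fully_formed_complex_peaks_in_alkaline_range(models):
    """The MnL species maximum falls between pH 8 and 10 at study conditions."""
    model = models["Mn_L1"]
    grid = np.arange(2.0, 11.01, 0.1)
    pts = speciation_table(model, {"Mn": 5e-4, "L1": 5.5e-4}, grid, reference="Mn")
    key = model.find_species(Mn=1, L1=1).key
    fractions = [pt.fractions.get(key, 0.0) for pt in pts]
    peak_ph = grid[int(np.argmax(fractions))]
    assert 8.0 <= peak_ph <= 10.0


def test_fully_protonated_ligand_dominates_acidic_end(models):
    model = models["L5"]
    pt = solve_free_concentrations(model, {"L5": 5e-4}, 2.0, reference="L5")
    species_fracs = {k: v for k, v in pt.fractions.items() if k != "free"}
    dominant = max(species_fracs, key=species_fracs.get)
    assert dict(dominant)["H"] == 9  # H9L5 is the fully protonated form


def test_empty_species_model_gives_free_fraction_one():
    model = EquilibriumModel(
        label="t",
        components=[Component("M", "metal"), Component("H", "proton")],
        species=[],
    )
    pt = solve_free_concentrations(model, {"M": 1e-3}, 7.0, reference="M")
    assert pt.fractions == {"free": pytest.approx(1.0)}


def test_solver_determinism(models):
    model = models["Fe_L2"]
    totals = {"Fe": 5e-4, "L2": 5.5e-4}
    a = solve_free_concentrations(model, totals, 7.3)
    b = solve_free_concentrations(model, totals, 7.3)
    assert a.free == b.free and a.species_conc == b.species_conc


def test_grid_refinement_is_pointwise(models):
    model = models["Mn_L5"]
    totals = {"Mn": 5e-4, "L5": 5.5e-4}
    coarse = speciation_table(model, totals, np.arange(3.0, 9.01, 0.4), reference="Mn")
    fine = speciation_table(model, totals, np.arange(3.0, 9.01, 0.2), reference="Mn")
    for pt_c, pt_f in zip(coarse, fine[::2]):
        assert pt_c.pH == pytest.approx(pt_f.pH, abs=1e-12)
        for key, value in pt_c.species_conc.items():
            assert value == pytest.approx(pt_f.species_conc[key], rel=1e-9)


class TestConditionalKd:
    def test_unprotonated_1to1_is_inverse_beta(self, ml_model):
        assert conditional_kd(ml_model, 5.0) == pytest.approx(1e-5, rel=1e-12)
        assert conditional_kd(ml_model, 9.0) == pytest.approx(1e-5, rel=1e-12)

    def test_oracle_trivial_case(self, ml_model):
        assert kd_half_bound_oracle(ml_model, 7.0) == pytest.approx(1e-5, rel=1e-6)

    def test_no_1to1_species_errors(self, hl_model):
        with pytest.raises(ModelError):
            conditional_kd(hl_model, 7.0)

    @pytest.mark.parametrize("label", ["Mn_L3", "Fe_L5", "Zn_L1"])
    def test_agrees_with_half_bound_oracle(self, models, label):
        for ph in (5.0, 7.0, 9.0):
            kd = conditional_kd(models[label], ph)
            assert kd_half_bound_oracle(models[label], ph) == pytest.approx(
                kd, rel=1e-6
            )

    def test_positive_and_continuous_over_ph_range(self, models):
        grid = np.arange(2.0, 11.01, 0.1)
        for label, model in models.items():
            if "_" not in label:
                continue
            values = np.array([conditional_kd(model, ph) for ph in grid])
            assert np.all(np.isfinite(values)) and np.all(values > 0), label
            steps = np.abs(np.diff(np.log10(values)))
            assert steps.max() < 1.0, label  # no jumps on a 0.1 pH grid

    def test_hydrolysis_side_reaction_scales_kd(self, ml_model):
        model = EquilibriumModel(
            label="t",
            components=list(ml_model.components),
            species=list(ml_model.species)
            + [FormationSpecies({"M": 1, "H": -1}, -9.0)],
        )
        ph = 10.0
        alpha = hydrolysis_alpha(model, 10.0**-ph)
        assert alpha == pytest.approx(1.0 + 10.0 ** (-9.0 + ph), rel=1e-12)
        assert conditional_kd(model, ph, include_hydrolysis=True) == pytest.approx(
            alpha * conditional_kd(model, ph), rel=1e-12
        )


class TestCompetition:
    def test_single_ligand_is_conservation(self, models):
        grid = np.arange(3.0, 10.01, 0.5)
        profile = competition_profile([models["Mn_L3"]], 1e-3, grid)
        assert np.allclose(profile.bound["L3"] + profile.unbound, 1.0, atol=1e-9)

    def test_bound_plus_free_sums_to_one(self, models):
        grid = np.arange(3.0, 10.01, 0.5)
        systems = [models[f"Fe_{l}"] for l in ("L2", "L3", "L5", "L6")]
        profile = competition_profile(systems, 1e-3, grid)
        total = profile.unbound + sum(profile.bound.values())
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_ligand_name_collision_errors(self, models):
        with pytest.raises(ModelError, match="collision"):
            merge_models([models["Mn_L3"], models["Mn_L3"]])

    def test_crossover_interpolation(self, models):
        systems = [models[f"Mn_{l}"] for l in ("L2", "L5")]
        profile = competition_profile(systems, 1e-3, np.arange(4.0, 8.01, 0.25))
        # Asp-rich L5 wins in acid, the long poly-His L2 wins at neutral pH:
        # exactly one dominance change on this window
        assert len(profile.crossovers) == 1
        ph_x, frm, to = profile.crossovers[0]
        assert frm == "L5" and to == "L2"
        assert 4.0 < ph_x < 8.0
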
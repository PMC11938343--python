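import numpy as np
import pytest

from equispec import (
    CalibrationError,
    Component,
    ElectrodeParams,
    EquilibriumModel,
    FormationSpecies,
    GranError,
    ModelError,
    TitrationDataset,
    TitrationProtocol,
    calibrate_electrode,
    gran_endpoint,
    simulate_titration,
    strong_acid_model,
)

ELECTRODE = ElectrodeParams(E0_mV=400.0, slope_mV=59.16)


def strong_acid_protocol(n=101, v_max=0.2):
    # 3 mL of 4 mM strong acid titrated with 0.1 M strong base: Veq = 0.120 mL
    return TitrationProtocol(
        initial_volume_mL=3.0,
        initial_totals={"H": 4e-3},
        titrant_concentration_M=0.1,
        volume_points_mL=np.linspace(0.0, v_max, n)[1:],
    )


def test_strong_acid_neutral_at_equivalence():
    model = strong_acid_model(pKw=14.0)
    protocol = TitrationProtocol(
        initial_volume_mL=3.0,
        initial_totals={"H": 4e-3},
        titrant_concentration_M=0.1,
        volume_points_mL=np.array([0.06, 0.09, 0.120, 0.15]),
    )
    dataset = simulate_titration(model, protocol)
    assert dataset.values[2] == pytest.approx(7.00, abs=1e-6)


def test_buffer_midpoint_reads_the_pka(hl_model):
    # ligand delivered fully protonated: the proton total equals the ligand
    # total, so half-equivalence leaves [L] = [HL] and pH = pKa
    protocol = TitrationProtocol(
        initial_volume_mL=3.0,
        initial_totals={"L": 1e-3, "H": 1e-3},
        titrant_concentration_M=0.1,
        volume_points_mL=np.array([0.005, 0.010, 0.015, 0.020, 0.025]),
    )
    dataset = simulate_titration(hl_model, protocol)
    assert dataset.values[2] == pytest.approx(7.00, abs=0.01)


def test_metal_titration_monotone_and_mass_balanced(models):
    from equispec import Scenario, solve_free_concentrations

    model = models["Mn_L3"]
    protocol = Scenario("Mn_L3", n_points=50, sigma_obs=0.0).to_protocol(model)
    dataset = simulate_titration(model, protocol)
    assert np.all(np.diff(dataset.values) > 0)
    # audit: at each simulated pH the fixed-pH solve must reproduce the
    # diluted metal/ligand totals and the full proton balance
    kw = 10.0**-model.pKw
    for v, ph in list(zip(dataset.volumes_mL, dataset.values))[::7]:
        totals = protocol.totals_at(v)
        pt = solve_free_concentrations(
            model, {k: c for k, c in totals.items() if k != "H"}, ph
        )
        for name in ("Mn", "L3"):
            recomputed = pt.free[name] + sum(
                dict(key).get(name, 0) * conc
                for key, conc in pt.species_conc.items()
            )
            assert recomputed == pytest.approx(totals[name], rel=1e-9)
        h = 10.0**-ph
        th = (
            h
            - kw / h
            + sum(
                dict(key).get("H", 0) * conc
                for key, conc in pt.species_conc.items()
            )
        )
        assert th == pytest.approx(totals["H"], rel=1e-6)


def test_dilution_conserves_component_moles():
    protocol = TitrationProtocol(
        initial_volume_mL=3.0,
        initial_totals={"M": 5e-4, "L": 5.5e-4, "H": 4e-3},
        titrant_concentration_M=0.1,
        volume_points_mL=np.linspace(0.01, 1.0, 20),
    )
    for v in protocol.volume_points_mL:
        totals = protocol.totals_at(v)
        for name in ("M", "L"):
            moles = totals[name] * (3.0 + v)
            assert moles == pytest.approx(
                protocol.initial_totals[name] * 3.0, rel=1e-12
            )


class TestGran:
    def test_noiseless_strong_acid_endpoint(self):
        model = strong_acid_model()
        protocol = strong_acid_protocol()
        dataset = simulate_titration(model, protocol, ELECTRODE)
        result = gran_endpoint(dataset, 3.0, electrode=ELECTRODE, branch="acid")
        assert result.equivalence_volume_mL == pytest.approx(0.1200, abs=1e-4)
        assert result.stderr_mL < 1e-6

    def test_base_branch_recovers_same_endpoint(self):
        model = strong_acid_model()
        protocol = strong_acid_protocol()
        dataset = simulate_titration(model, protocol)  # pH kind
        result = gran_endpoint(dataset, 3.0, branch="base", pKw=model.pKw)
        assert result.equivalence_volume_mL == pytest.approx(0.1200, rel=1e-3)

    def test_exact_collinear_points(self):
        # Gran function linear by construction, zero-crossing at V = 1.000
        v = np.array([0.2, 0.4, 0.6, 0.8])
        f = 1.0 - v  # = (V0+V)*h up to a constant factor
        ph = -np.log10(f / (3.0 + v))
        dataset = TitrationDataset(v, ph, "pH")
        result = gran_endpoint(dataset, 3.0, branch="acid", window=(0.0, 1.0))
        assert result.equivalence_volume_mL == pytest.approx(1.000, abs=1e-9)

    def test_noisy_endpoint_within_one_percent(self):
        model = strong_acid_model()
        protocol = strong_acid_protocol()
        clean = simulate_titration(model, protocol, ELECTRODE)
        rng = np.random.default_rng(20260301)
        noisy = TitrationDataset(
            clean.volumes_mL, clean.values + rng.normal(0.0, 0.1, len(clean)), "emf_mV"
        )
        result = gran_endpoint(noisy, 3.0, electrode=ELECTRODE, branch="acid")
        assert result.equivalence_volume_mL == pytest.approx(0.1200, rel=0.01)

    def test_non_monotone_window_errors(self):
        v = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        ph = np.array([2.0, 2.6, 2.2, 2.9, 3.4])  # wiggly: F not monotone
        with pytest.raises(GranError, match="window"):
            gran_endpoint(TitrationDataset(v, ph, "pH"), 3.0, window=(0.0, 1.0))


class TestCalibration:
    def test_noiseless_recovery_to_four_significant_figures(self):
        model = strong_acid_model()
        protocol = strong_acid_protocol()
        dataset = simulate_titration(model, protocol, ELECTRODE)
        cal = calibrate_electrode(dataset, protocol, pKw=model.pKw)
        assert cal.E0_mV == pytest.approx(400.0, abs=5e-2)
        assert cal.slope_mV == pytest.approx(59.16, abs=5e-3)

    def test_noisy_recovery_within_three_stderr(self):
        model = strong_acid_model()
        protocol = strong_acid_protocol()
        clean = simulate_titration(model, protocol, ELECTRODE)
        rng = np.random.default_rng(5)
        noisy = TitrationDataset(
            clean.volumes_mL, clean.values + rng.normal(0.0, 0.1, len(clean)), "emf_mV"
        )
        cal = calibrate_electrode(noisy, protocol, pKw=model.pKw)
        assert abs(cal.E0_mV - 400.0) < 3 * cal.sigma_E0
        assert abs(cal.slope_mV - 59.16) < 3 * cal.sigma_slope

    def test_ph_dataset_is_rejected(self):
        model = strong_acid_model()
        protocol = strong_acid_protocol()
        dataset = simulate_titration(model, protocol)  # pH kind
        with pytest.raises(CalibrationError, match="emf"):
            calibrate_electrode(dataset, protocol)

    def test_protocol_with_ligand_is_rejected(self, hl_model):
        protocol = TitrationProtocol(
            initial_volume_mL=3.0,
            initial_totals={"L": 1e-3, "H": 4e-3},
            titrant_concentration_M=0.1,
            volume_points_mL=np.linspace(0.01, 0.2, 30),
        )
        dataset = simulate_titration(hl_model, protocol, ELECTRODE)
        with pytest.raises(CalibrationError, match="strong acid only"):
            calibrate_electrode(dataset, protocol)


class TestDatasetInvariants:
    def test_minimum_points(self):
        with pytest.raises(ModelError, match="at least 4"):
            TitrationDataset(np.array([0.1, 0.2, 0.3]), np.zeros(3), "pH")

    def test_monotone_volumes(self):
        with pytest.raises(ModelError, match="strictly increasing"):
            TitrationDataset(np.array([0.1, 0.3, 0.2, 0.4]), np.zeros(4), "pH")

    def test_kind_vocabulary(self):
        with pytest.raises(ModelError, match="kind"):
            TitrationDataset(np.linspace(0, 1, 5), np.zeros(5), "volts")
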
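import pytest

from equispec import (
    Component,
    EquilibriumModel,
    FormationSpecies,
    paper_fixture_models,
)


@pytest.fixture(scope="session")
def models():
    """All packaged constant-table models, keyed by label."""
    return paper_fixture_models()


@pytest.fixture()
def hl_model():
    """Minimal monoprotic ligand: HL with log beta = 7.00."""
    return EquilibriumModel(
        label="HL",
        components=[Component("L", "ligand"), Component("H", "proton")],
        species=[FormationSpecies({"L": 1, "H": 1}, 7.00)],
    )


@pytest.fixture()
def ml_model():
    """Minimal 1:1 complex: ML with log beta = 5.00, no ligand protonation."""
    return EquilibriumModel(
        label="ML",
        components=[
            Component("M", "metal"),
            Component("L", "ligand"),
            Component("H", "proton"),
        ],
        species=[FormationSpecies({"M": 1, "L": 1}, 5.00)],
    )
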
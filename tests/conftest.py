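import numpy as np
import pytest

from urisat.constants import ComplexDef, ConstantsSet, FreeSpecies, SaltDef, load_constants
from urisat.speciation import UrinePanel

# silence the optional-analyte default warnings in test logs
import logging

logging.getLogger("urisat").setLevel(logging.ERROR)


def zero_totals() -> dict[str, float]:
    return {a: 0.0 for a in ("Ca", "Mg", "Na", "K", "NH4", "Cl", "SO4", "PO4", "Ox", "Cit", "Ur", "PyroP", "CO3")}


def make_panel(sample_id="s1", ph=6.0, **conc) -> UrinePanel:
    totals = zero_totals()
    totals.update(conc)
    return UrinePanel(sample_id=sample_id, ph=ph, totals=totals)


@pytest.fixture(scope="session")
def default_constants() -> ConstantsSet:
    return load_constants("default")


@pytest.fixture()
def caox_species() -> list[FreeSpecies]:
    return [
        FreeSpecies("Ca", 2, is_component=True),
        FreeSpecies("Ox", -2, is_component=True),
        FreeSpecies("H", 1, is_component=True),
    ]


@pytest.fixture()
def no_complex_registry(caox_species) -> ConstantsSet:
    """Ideal toy system: Ca/Ox components, no complexes, both salts present."""
    return ConstantsSet(
        species=[
            *caox_species,
            FreeSpecies("Mg", 2, is_component=True),
            FreeSpecies("NH4", 1, is_component=True),
            FreeSpecies("PO4", -3, is_component=True),
            FreeSpecies("Na", 1, is_component=True),
            FreeSpecies("K", 1, is_component=True),
            FreeSpecies("Cl", -1, is_component=True),
            FreeSpecies("SO4", -2, is_component=True),
            FreeSpecies("Cit", -3, is_component=True),
            FreeSpecies("Ur", -1, is_component=True),
            FreeSpecies("PyroP", -4, is_component=True),
            FreeSpecies("CO3", -2, is_component=True),
        ],
        complexes=[],
        salts=[
            SaltDef("caox", {"Ca": 1, "Ox": 1}, log_ksp=-8.65),
            SaltDef("struvite", {"Mg": 1, "NH4": 1, "PO4": 1}, log_ksp=-13.26),
        ],
        name="toy-ideal",
    )


@pytest.fixture()
def caox_complex_registry(caox_species) -> ConstantsSet:
    """Ca + Ox with one 1:1 complex — analytically solvable (quadratic)."""
    return ConstantsSet(
        species=caox_species,
        complexes=[ComplexDef("CaOx_aq", {"Ca": 1, "Ox": 1}, charge=0, log_beta=3.19)],
        salts=[SaltDef("caox", {"Ca": 1, "Ox": 1}, log_ksp=-8.65)],
        name="toy-caox",
    )


@pytest.fixture()
def three_component_registry(caox_species) -> ConstantsSet:
    """Ca, Ox and fixed-pH protonation: HOx, H2Ox, CaOx_aq."""
    return ConstantsSet(
        species=caox_species,
        complexes=[
            ComplexDef("HOx", {"H": 1, "Ox": 1}, charge=-1, log_beta=4.27),
            ComplexDef("H2Ox", {"H": 2, "Ox": 1}, charge=0, log_beta=5.52),
            ComplexDef("CaOx_aq", {"Ca": 1, "Ox": 1}, charge=0, log_beta=3.19),
        ],
        salts=[SaltDef("caox", {"Ca": 1, "Ox": 1}, log_ksp=-8.65)],
        name="toy-3comp",
    )


def random_small_registry(rng: np.random.Generator) -> ConstantsSet:
    """Randomized <=4-component system with random 1:1/protonated complexes."""
    species = [
        FreeSpecies("Ca", 2, is_component=True),
        FreeSpecies("Ox", -2, is_component=True),
        FreeSpecies("Cit", -3, is_component=True),
        FreeSpecies("Na", 1, is_component=True),
        FreeSpecies("H", 1, is_component=True),
    ]
    complexes = []
    candidates = [
        ("CaOx_aq", {"Ca": 1, "Ox": 1}, 0, (2.0, 4.0)),
        ("CaCit", {"Ca": 1, "Cit": 1}, -1, (3.0, 5.5)),
        ("HOx", {"H": 1, "Ox": 1}, -1, (3.5, 4.8)),
        ("HCit", {"H": 1, "Cit": 1}, -2, (5.5, 6.8)),
        ("H2Cit", {"H": 2, "Cit": 1}, -1, (10.0, 12.0)),
        ("NaOx", {"Na": 1, "Ox": 1}, -1, (0.5, 1.5)),
        ("NaCit", {"Na": 1, "Cit": 1}, -2, (1.0, 2.0)),
        ("CaOH", {"Ca": 1, "H": -1}, 1, (-12.8, -12.0)),
    ]
    for cid, stoich, charge, (lo, hi) in candidates:
        if rng.random() < 0.7:
            complexes.append(ComplexDef(cid, stoich, charge=charge, log_beta=float(rng.uniform(lo, hi))))
    return ConstantsSet(
        species=species,
        complexes=complexes,
        salts=[SaltDef("caox", {"Ca": 1, "Ox": 1}, log_ksp=-8.65)],
        name="toy-random",
    )


def random_small_panel(rng: np.random.Generator) -> UrinePanel:
    totals = zero_totals()
    totals["Ca"] = float(10.0 ** rng.uniform(-1.5, 1.0))   # 0.03–10 mmol/L
    totals["Ox"] = float(10.0 ** rng.uniform(-2.0, 0.5))
    totals["Cit"] = float(10.0 ** rng.uniform(-1.5, 1.0))
    totals["Na"] = float(10.0 ** rng.uniform(0.0, 2.3))
    return UrinePanel(sample_id="rnd", ph=float(rng.uniform(4.5, 8.5)), totals=totals)
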
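"""Thermodynamic constants registry: species, complexes, salts.

The speciation solver is parameterized entirely by a :class:`ConstantsSet` —
the free species it tracks, the soluble complexes with their cumulative
formation constants (log10 beta, activity scale), and the sparingly soluble
salts with their thermodynamic solubility products (log10 Ksp).  The package
ships a default registry reconstructed from open critical-stability-constant
compilations, but every coefficient is visible, sourced, and swappable: load
a different YAML registry and the whole pipeline recomputes against it.

Conventions
-----------
* ``H`` is a component species whose activity is fixed by the measured pH;
  it carries no mass balance.  A negative H count in a complex stoichiometry
  encodes hydroxide association, so the water ion product itself appears as
  the complex ``OH`` with stoichiometry ``{H: -1}``.
* Constants are stored on the log10 scale only (log_beta, log_ksp), at the
  registry's single reference temperature (default 38 °C, body temperature).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "FreeSpecies",
    "ComplexDef",
    "SaltDef",
    "ConstantsSet",
    "RegistryError",
    "load_constants",
    "write_constants",
    "perturb_constants",
    "validate_registry_mapping",
]

REGISTRY_FORMAT = "urisat-constants-v1"


class RegistryError(ValueError):
    """Malformed or inconsistent constants registry."""


@dataclass(frozen=True)
class FreeSpecies:
    """A free (uncomplexed) aqueous species.

    Parameters
    ----------
    id : str
        Short name, e.g. ``"Ca"``, ``"Ox"``, ``"PO4"``, ``"H"``.
    charge : int
        Signed charge in elementary units.
    is_component : bool
        True for species whose total concentration is a user input.  ``"H"``
        is special: it is a component whose activity is fixed by pH and which
        carries no mass balance.
    provenance : str
        Free-text source note.
    """

    id: str
    charge: int
    is_component: bool = False
    provenance: str = ""


@dataclass(frozen=True)
class ComplexDef:
    """A soluble complex formed from component species.

    ``stoich`` maps component id -> signed integer count; protons enter via
    component ``"H"`` and a negative H count encodes hydroxide association.
    ``log_beta`` is the cumulative base-10 formation constant on the activity
    scale at the registry's reference temperature.
    """

    id: str
    stoich: Mapping[str, int]
    charge: int
    log_beta: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.stoich:
            raise RegistryError(f"complex {self.id!r}: empty stoichiometry")
        if not math.isfinite(self.log_beta):
            raise RegistryError(f"complex {self.id!r}: non-finite log_beta")
        object.__setattr__(self, "stoich", dict(self.stoich))


@dataclass(frozen=True)
class SaltDef:
    """A sparingly soluble salt with its thermodynamic solubility product.

    ``lattice_stoich`` maps component id -> positive integer count of that ion
    in the lattice formula unit.  Water of crystallization carries activity 1
    and never enters the ion activity product, so it is not recorded here.
    """

    id: str
    lattice_stoich: Mapping[str, int]
    log_ksp: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.lattice_stoich:
            raise RegistryError(f"salt {self.id!r}: empty lattice stoichiometry")
        if any(n <= 0 for n in self.lattice_stoich.values()):
            raise RegistryError(f"salt {self.id!r}: lattice counts must be positive")
        if not math.isfinite(self.log_ksp):
            raise RegistryError(f"salt {self.id!r}: non-finite log_ksp")
        object.__setattr__(self, "lattice_stoich", dict(self.lattice_stoich))


@dataclass
class ConstantsSet:
    """A validated, order-preserving registry of species, complexes, salts."""

    species: list[FreeSpecies]
    complexes: list[ComplexDef]
    salts: list[SaltDef]
    reference_temperature: float = 38.0
    name: str = "unnamed"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------

    def species_by_id(self) -> dict[str, FreeSpecies]:
        return {s.id: s for s in self.species}

    def complex_by_id(self) -> dict[str, ComplexDef]:
        return {c.id: c for c in self.complexes}

    def salt_by_id(self) -> dict[str, SaltDef]:
        return {s.id: s for s in self.salts}

    @property
    def component_ids(self) -> list[str]:
        """Component species ids excluding the pH-clamped proton."""
        return [s.id for s in self.species if s.is_component and s.id != "H"]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Cross-reference and charge-balance checks; raises RegistryError."""
        problems: list[str] = []
        seen: set[str] = set()
        for s in self.species:
            if s.id in seen:
                problems.append(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        charges = {s.id: s.charge for s in self.species}

        seen_cx: set[str] = set()
        for c in self.complexes:
            if c.id in seen_cx:
                problems.append(f"duplicate complex id {c.id!r}")
            seen_cx.add(c.id)
            missing = [j for j in c.stoich if j not in charges]
            if missing:
                problems.append(f"complex {c.id!r}: unknown components {missing}")
                continue
            z = sum(n * charges[j] for j, n in c.stoich.items())
            if z != c.charge:
                problems.append(
                    f"complex {c.id!r}: declared charge {c.charge} but "
                    f"stoichiometry sums to {z}"
                )
        for salt in self.salts:
            missing = [j for j in salt.lattice_stoich if j not in charges]
            if missing:
                problems.append(f"salt {salt.id!r}: unknown lattice ions {missing}")
                continue
            z = sum(n * charges[j] for j, n in salt.lattice_stoich.items())
            if z != 0:
                problems.append(
                    f"salt {salt.id!r}: lattice is not electroneutral (net charge {z})"
                )
        if problems:
            raise RegistryError("registry validation failed:\n  " + "\n  ".join(problems))


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def validate_registry_mapping(doc: object, source: str = "<registry>") -> dict:
    """Structural check of a parsed registry document against the shipped schema.

    Implements the constraints of ``data/constants.schema.json`` directly so no
    external schema-validation dependency is needed; the JSON-schema file is
    shipped alongside for machine consumption by other tools.
    """
    if not isinstance(doc, dict):
        raise RegistryError(f"{source}: registry document must be a mapping")
    if doc.get("format") != REGISTRY_FORMAT:
        raise RegistryError(
            f"{source}: missing or unsupported 'format' (expected {REGISTRY_FORMAT!r})"
        )
    for block in ("species", "complexes", "salts"):
        if block not in doc:
            raise RegistryError(f"{source}: missing block {block!r}")
        if not isinstance(doc[block], list):
            raise RegistryError(f"{source}: block {block!r} must be a list")
    for i, entry in enumerate(doc["species"]):
        _require_keys(entry, {"id", "charge"}, f"{source}: species[{i}]")
    for i, entry in enumerate(doc["complexes"]):
        _require_keys(entry, {"id", "stoich", "charge", "log_beta"}, f"{source}: complexes[{i}]")
        if not isinstance(entry["stoich"], dict) or not entry["stoich"]:
            raise RegistryError(f"{source}: complexes[{i}] ({entry.get('id')}): bad stoich")
    for i, entry in enumerate(doc["salts"]):
        _require_keys(entry, {"id", "lattice", "log_ksp"}, f"{source}: salts[{i}]")
        if not isinstance(entry["lattice"], dict) or not entry["lattice"]:
            raise RegistryError(f"{source}: salts[{i}] ({entry.get('id')}): bad lattice")
    return doc


def _require_keys(entry: object, keys: set[str], where: str) -> None:
    if not isinstance(entry, dict):
        raise RegistryError(f"{where}: entry must be a mapping")
    missing = keys - entry.keys()
    if missing:
        raise RegistryError(f"{where}: missing keys {sorted(missing)}")


def _from_mapping(doc: dict, source: str) -> ConstantsSet:
    validate_registry_mapping(doc, source)
    species = [
        FreeSpecies(
            id=str(e["id"]),
            charge=int(e["charge"]),
            is_component=bool(e.get("component", False)),
            provenance=str(e.get("provenance", "")),
        )
        for e in doc["species"]
    ]
    complexes = [
        ComplexDef(
            id=str(e["id"]),
            stoich={str(k): int(v) for k, v in e["stoich"].items()},
            charge=int(e["charge"]),
            log_beta=float(e["log_beta"]),
            provenance=str(e.get("provenance", "")),
        )
        for e in doc["complexes"]
    ]
    salts = [
        SaltDef(
            id=str(e["id"]),
            lattice_stoich={str(k): int(v) for k, v in e["lattice"].items()},
            log_ksp=float(e["log_ksp"]),
            provenance=str(e.get("provenance", "")),
        )
        for e in doc["salts"]
    ]
    return ConstantsSet(
        species=species,
        complexes=complexes,
        salts=salts,
        reference_temperature=float(doc.get("reference_temperature", 38.0)),
        name=str(doc.get("name", source)),
    )


def load_constants(path_or_name: str | Path = "default") -> ConstantsSet:
    """Load and validate a constants registry.

    Parameters
    ----------
    path_or_name : str or Path
        ``"default"`` for the packaged registry, otherwise a path to a YAML
        registry file in the documented ``urisat-constants-v1`` format.

    Returns
    -------
    ConstantsSet
        Validated, order-preserving registry.

    Raises
    ------
    RegistryError
        On parse failure, missing keys, unresolved cross-references, complex
        charge-balance violations, or non-electroneutral salt lattices.
    """
    if str(path_or_name) == "default":
        text = resources.files("urisat.data").joinpath("default_constants.yaml").read_text()
        source = "default"
    else:
        p = Path(path_or_name)
        if not p.exists():
            raise RegistryError(f"registry file not found: {p}")
        text = p.read_text()
        source = str(p)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # carries the line/column mark
        raise RegistryError(f"{source}: YAML parse error: {exc}") from exc
    return _from_mapping(doc, source)


def write_constants(cset: ConstantsSet, path: str | Path) -> Path:
    """Serialize a ConstantsSet to the YAML registry format (round-trippable)."""
    doc = {
        "format": REGISTRY_FORMAT,
        "name": cset.name,
        "reference_temperature": cset.reference_temperature,
        "species": [
            {
                "id": s.id,
                "charge": s.charge,
                "component": s.is_component,
                "provenance": s.provenance,
            }
            for s in cset.species
        ],
        "complexes": [
            {
                "id": c.id,
                "stoich": dict(c.stoich),
                "charge": c.charge,
                "log_beta": c.log_beta,
                "provenance": c.provenance,
            }
            for c in cset.complexes
        ],
        "salts": [
            {
                "id": s.id,
                "lattice": dict(s.lattice_stoich),
                "log_ksp": s.log_ksp,
                "provenance": s.provenance,
            }
            for s in cset.salts
        ],
    }
    p = Path(path)
    p.write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=None))
    return p


# ---------------------------------------------------------------------------
# perturbation (emulating a second program's coefficient set)
# ---------------------------------------------------------------------------


def perturb_constants(
    base: ConstantsSet,
    salt_scale: Mapping[str, float] | None = None,
    beta_shift: Mapping[str, float] | None = None,
) -> ConstantsSet:
    """Return an independent copy of ``base`` with shifted constants.

    Emulates a second speciation program whose coefficient set differs from the
    first by known amounts — the mechanism that produces constant-slope,
    high-r² disagreement between RSS programs.

    Parameters
    ----------
    salt_scale : mapping salt-id -> positive factor
        Each salt's log_ksp becomes ``log_ksp - log10(factor)``; i.e. its Ksp
        is divided by the factor, so the salt's RSS is multiplied by it.
    beta_shift : mapping complex-id -> additive log10 shift
        Each complex's log_beta becomes ``log_beta + shift``.
    """
    salt_scale = dict(salt_scale or {})
    beta_shift = dict(beta_shift or {})

    salt_ids = {s.id for s in base.salts}
    unknown = set(salt_scale) - salt_ids
    if unknown:
        raise KeyError(f"unknown salt ids in salt_scale: {sorted(unknown)}")
    cx_ids = {c.id for c in base.complexes}
    unknown = set(beta_shift) - cx_ids
    if unknown:
        raise KeyError(f"unknown complex ids in beta_shift: {sorted(unknown)}")
    for sid, f in salt_scale.items():
        if not (f > 0 and math.isfinite(f)):
            raise ValueError(f"salt_scale[{sid!r}] must be positive and finite, got {f}")
    for cid, d in beta_shift.items():
        if not math.isfinite(d):
            raise ValueError(f"beta_shift[{cid!r}] must be finite, got {d}")

    new = copy.deepcopy(base)
    new.salts = [
        SaltDef(
            id=s.id,
            lattice_stoich=dict(s.lattice_stoich),
            log_ksp=s.log_ksp - math.log10(salt_scale[s.id]) if s.id in salt_scale else s.log_ksp,
            provenance=s.provenance,
        )
        for s in base.salts
    ]
    new.complexes = [
        ComplexDef(
            id=c.id,
            stoich=dict(c.stoich),
            charge=c.charge,
            log_beta=c.log_beta + beta_shift.get(c.id, 0.0),
            provenance=c.provenance,
        )
        for c in base.complexes
    ]
    if salt_scale or beta_shift:
        new.name = f"{base.name}+perturbed"
    return new
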
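"""Ion activity products and relative supersaturation (RSS).

RSS for a salt is the ratio of its ion activity product (IAP) in the sample
to its thermodynamic solubility product (Ksp): RSS = 1 marks saturation,
> 1 supersaturation (crystallization thermodynamically possible), < 1
undersaturation (existing crystals can dissolve).  The package certifies
calcium oxalate (whewellite) and struvite (magnesium ammonium phosphate
hexahydrate); any salt present in the loaded registry can be evaluated.

RSS is reported as the raw activity-product ratio IAP/Ksp.  A per-ion
(nth-root) variant, sometimes used to put salts with different lattice sizes
on a comparable scale, is available as :func:`rss_nth_root`; mixing the two
conventions between programs is itself a source of slope-like disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import ConstantsSet, SaltDef
from .speciation import SolverOptions, SpeciationResult, UrinePanel, solve_speciation

__all__ = ["SaltRecord", "RSSResult", "ion_activity_product", "compute_rss", "rss_nth_root"]

DEFAULT_SALTS = ("caox", "struvite")


@dataclass(frozen=True)
class SaltRecord:
    """Per-salt supersaturation record: IAP, registry log Ksp, RSS ratio."""

    salt_id: str
    iap: float
    log_ksp: float
    rss: float


@dataclass
class RSSResult:
    """RSS outcome for one sample, with the underlying speciation attached."""

    sample_id: str
    salts: dict[str, SaltRecord]
    speciation: SpeciationResult

    def rss(self, salt_id: str) -> float:
        return self.salts[salt_id].rss


def ion_activity_product(spec: SpeciationResult, salt: SaltDef) -> float:
    """IAP = product over lattice ions of activity**stoich (molar activity scale).

    Water of crystallization carries activity 1 and contributes nothing.
    A zero activity for any lattice ion gives IAP = 0.
    """
    iap = 1.0
    for ion, n in salt.lattice_stoich.items():
        if ion not in spec.activities:
            raise KeyError(
                f"salt {salt.id!r}: lattice ion {ion!r} absent from speciation result"
            )
        iap *= spec.activities[ion] ** n
    return iap


def rss_nth_root(record: SaltRecord, salt: SaltDef) -> float:
    """(IAP/Ksp)**(1/n) with n the number of ions in the lattice formula unit."""
    n = sum(salt.lattice_stoich.values())
    return record.rss ** (1.0 / n)


def compute_rss(
    panel: UrinePanel,
    constants: ConstantsSet,
    opts: SolverOptions = SolverOptions(),
    salts: tuple[str, ...] | list[str] = DEFAULT_SALTS,
) -> RSSResult:
    """Speciate one sample and evaluate RSS = IAP / 10**log_ksp per salt.

    Raises KeyError for salts not in the registry; solver non-convergence
    propagates (with the sample id in the message) under strict options.
    """
    by_id = constants.salt_by_id()
    missing = [s for s in salts if s not in by_id]
    if missing:
        raise KeyError(f"salts not in registry {constants.name!r}: {missing}")
    spec = solve_speciation(panel, constants, opts)
    records: dict[str, SaltRecord] = {}
    for sid in salts:
        salt = by_id[sid]
        iap = ion_activity_product(spec, salt)
        rss = iap / 10.0 ** salt.log_ksp
        records[sid] = SaltRecord(salt_id=sid, iap=iap, log_ksp=salt.log_ksp, rss=rss)
    return RSSResult(sample_id=panel.sample_id, salts=records, speciation=spec)
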
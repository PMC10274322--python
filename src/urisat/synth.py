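"""Synthetic canine and feline 24-h urine panels.

No public repository of paired canine/feline urine-chemistry panels exists
at study scale, so the rest of the package is exercised end-to-end on
synthetic cohorts.  Analyte concentrations are drawn from log-normal
marginals (urinary ion concentrations are strictly positive and
right-skewed), pH from a truncated normal, optionally tied together by a
Gaussian copula when a rank-correlation matrix is supplied.  The shipped
presets emulate healthy adult laboratory beagles and shorthair cats; their
parameters come from published companion-animal urine reference intervals
(see :func:`preset`) and are calibrated qualitatively — right skew and
coefficient-of-variation order of magnitude — not to any particular cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .speciation import REQUIRED_ANALYTES, UrinePanel

__all__ = ["PanelDistribution", "preset", "generate_panels"]


@dataclass
class PanelDistribution:
    """Sampling distribution for one species' urine panels.

    analytes maps component id -> (median mmol/L, geometric SD); the
    geometric SD is the exp of the SD of log concentration (gsd = 1 means a
    point mass at the median).  ph is (mean, sd, low, high) for a truncated
    normal.  correlation, if given, is a rank-correlation matrix across the
    analytes in listed order, applied through a Gaussian copula.
    """

    species_label: str
    analytes: dict[str, tuple[float, float]]
    ph: tuple[float, float, float, float]
    correlation: np.ndarray | None = None
    _order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self._order = list(self.analytes)
        for a, (med, gsd) in self.analytes.items():
            if med <= 0:
                raise ValueError(f"{a}: median must be > 0, got {med}")
            if gsd < 1.0:
                raise ValueError(f"{a}: geometric SD must be >= 1, got {gsd}")
        mean, sd, lo, hi = self.ph
        if sd < 0 or not (4.0 <= lo < hi <= 9.0):
            raise ValueError(f"bad pH spec {self.ph}: need sd >= 0 and 4 <= lo < hi <= 9")
        missing = [a for a in REQUIRED_ANALYTES if a not in self.analytes]
        if missing:
            raise ValueError(f"distribution missing required analytes: {missing}")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(self._order)
            if R.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k}")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            evals = np.linalg.eigvalsh(R)
            if evals.min() < -1e-10:
                raise ValueError("correlation must be positive semi-definite")
            self.correlation = R


# Preset medians (mmol/L) and geometric SDs for 24-h urine from healthy adult
# animals.  Sources: canine/feline 24-h urinary analyte reference intervals in
# the veterinary urolithiasis literature (e.g. Stevenson & Markwell's healthy
# dog/cat urine composition tables; Lulich et al. reference ranges).  Cats void
# more concentrated urine at slightly lower pH; dogs show wider pH spread.
_PRESETS: dict[str, PanelDistribution] = {}


def _build_presets() -> None:
    _PRESETS["canine"] = PanelDistribution(
        species_label="canine",
        analytes={
            "Ca": (2.0, 1.8),
            "Mg": (2.0, 1.7),
            "Na": (80.0, 1.5),
            "K": (60.0, 1.5),
            "NH4": (30.0, 1.6),
            "Cl": (100.0, 1.5),
            "SO4": (15.0, 1.5),
            "PO4": (25.0, 1.6),
            "Ox": (0.30, 1.7),
            "Cit": (1.5, 2.0),
            "Ur": (1.0, 1.6),
            "PyroP": (0.03, 1.8),
            "CO3": (4.0, 2.0),  # total CO2; strongly pH-dependent in vivo
        },
        ph=(6.5, 0.55, 5.0, 8.5),
    )
    _PRESETS["feline"] = PanelDistribution(
        species_label="feline",
        analytes={
            "Ca": (1.6, 1.8),
            "Mg": (3.5, 1.7),
            "Na": (120.0, 1.5),
            "K": (90.0, 1.5),
            "NH4": (50.0, 1.6),
            "Cl": (150.0, 1.5),
            "SO4": (25.0, 1.5),
            "PO4": (40.0, 1.6),
            "Ox": (0.35, 1.7),
            "Cit": (1.2, 2.0),
            "Ur": (1.2, 1.6),
            "PyroP": (0.04, 1.8),
            "CO3": (4.0, 2.0),
        },
        ph=(6.4, 0.45, 5.2, 8.2),
    )


_build_presets()


def preset(species: str) -> PanelDistribution:
    """Return the documented default distribution for ``"canine"`` or ``"feline"``.

    The presets reproduce the qualitative statistical structure of healthy
    adult 24-h collections — strictly positive right-skewed analyte
    concentrations, pH roughly 5–8.5 — and give right-skewed RSS
    distributions whose coefficients of variation are of the same order as
    published cohort summaries (CaOx CV near 75%, struvite CV well above
    100%).  They are not a reconstruction of any specific cohort.
    """
    try:
        d = _PRESETS[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; expected 'canine' or 'feline'")
    # return an independent copy so callers can tweak freely
    return PanelDistribution(
        species_label=d.species_label,
        analytes=dict(d.analytes),
        ph=d.ph,
        correlation=None if d.correlation is None else d.correlation.copy(),
    )


def generate_panels(dist: PanelDistribution, n: int, seed: int) -> list[UrinePanel]:
    """Draw ``n`` urine panels from ``dist``; reproducible given (dist, n, seed).

    With no correlation matrix the analytes are independent; with one, a
    Gaussian copula imposes the requested rank correlation while preserving
    the log-normal marginals.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    order = dist._order
    k = len(order)
    if dist.correlation is not None:
        L = np.linalg.cholesky(dist.correlation + 1e-12 * np.eye(k))
        z = rng.standard_normal((n, k)) @ L.T
    else:
        z = rng.standard_normal((n, k))
    conc = np.zeros((n, k))
    for j, a in enumerate(order):
        med, gsd = dist.analytes[a]
        conc[:, j] = med * np.exp(np.log(gsd) * z[:, j])
    mean, sd, lo, hi = dist.ph
    if sd == 0:
        ph = np.full(n, mean)
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        ph = stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)
    panels = []
    for i in range(n):
        totals = {a: float(conc[i, j]) for j, a in enumerate(order)}
        panels.append(
            UrinePanel(
                sample_id=f"{dist.species_label}-{i:04d}",
                ph=float(ph[i]),
                totals=totals,
            )
        )
    return panels
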
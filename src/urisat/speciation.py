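"""Fixed-pH chemical speciation of a urine sample.

Given a sample's pH and the total (analytical) concentrations of its major
ions, solve the coupled mass-action / mass-balance system for the free
concentration of every component and the concentration of every soluble
complex, with Davies activity corrections made self-consistent with the
ionic strength of the converged solution.

Model
-----
The proton is special: urine pH is a direct glass-electrode measurement, so
the hydrogen-ion activity is clamped at ``a_H = 10**(-pH)`` and no proton
mass balance is written (hydroxide enters through the water ion product,
which the registry stores as the complex ``OH`` with stoichiometry
``{H: -1}``).  For every other component ``j`` with user-supplied total
``T_j`` (mol/L):

    T_j = [j] + sum_k n_kj [C_k]

and each complex obeys mass action on the activity scale:

    [C_k] = beta_k * prod_j a_j**n_kj / gamma_k,   a_j = gamma_j [j]

Numerics: an outer fixed-point iteration on ionic strength / activity
coefficients around an inner damped Newton iteration on log free
concentrations (log-space steps keep every concentration positive by
construction).  The result is contractually independent of this scheme:
tests cross-check it against a general-purpose root finder on the same
equations.

Units: user-facing totals and free concentrations are mmol/L; internal
thermodynamics are mol/L.  The conversion happens exactly once, at entry
and exit of :func:`solve_speciation`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import ConstantsSet

__all__ = [
    "UrinePanel",
    "SolverOptions",
    "SpeciationResult",
    "ConvergenceError",
    "REQUIRED_ANALYTES",
    "OPTIONAL_ANALYTES",
    "ionic_strength",
    "activity_coefficient",
    "solve_speciation",
]

logger = logging.getLogger(__name__)

#: the ten analytes measured on every sample (component ids)
REQUIRED_ANALYTES = ("Ca", "Mg", "Na", "K", "NH4", "Cl", "SO4", "PO4", "Ox", "Cit")
#: analytes that default to zero when not measured
OPTIONAL_ANALYTES = ("Ur", "PyroP", "CO3")

_MMOL_PER_MOL = 1000.0


class ConvergenceError(RuntimeError):
    """Speciation failed to converge within the iteration budget."""


@dataclass
class UrinePanel:
    """One urine sample: pH plus total analyte concentrations in mmol/L.

    ``totals`` maps component ids (``Ca``, ``Mg``, ``Na``, ``K``, ``NH4``,
    ``Cl``, ``SO4``, ``PO4``, ``Ox``, ``Cit`` required; ``Ur``, ``PyroP``,
    ``CO3`` optional) to total concentrations.  Missing optional analytes
    default to zero with a logged warning; pH outside [4, 9] warns, outside
    [2, 12] raises.
    """

    sample_id: str
    ph: float
    totals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (2.0 <= self.ph <= 12.0):
            raise ValueError(f"sample {self.sample_id!r}: pH {self.ph} outside [2, 12]")
        if not (4.0 <= self.ph <= 9.0):
            warnings.warn(
                f"sample {self.sample_id!r}: pH {self.ph} outside the physiological "
                "range [4, 9]",
                stacklevel=2,
            )
        missing = [a for a in REQUIRED_ANALYTES if a not in self.totals]
        if missing:
            raise ValueError(
                f"sample {self.sample_id!r}: missing required analytes {missing}"
            )
        negative = {k: v for k, v in self.totals.items() if v < 0}
        if negative:
            raise ValueError(
                f"sample {self.sample_id!r}: negative totals {negative}"
            )
        absent_optional = [a for a in OPTIONAL_ANALYTES if a not in self.totals]
        if absent_optional:
            logger.warning(
                "sample %r: optional analytes %s not supplied, defaulting to 0",
                self.sample_id,
                absent_optional,
            )
            for a in absent_optional:
                self.totals[a] = 0.0


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the speciation solver.

    davies_A is the Debye–Hückel limiting slope at the working temperature
    (0.5221 at 38 °C); davies_linear_term is the coefficient of the linear
    ionic-strength term in the Davies expression (classically 0.3).
    """

    tol_rel: float = 1e-9
    tol_mb: float = 1e-8
    max_iter: int = 200
    activity_model: str = "davies"  # "davies" | "ideal"
    davies_A: float = 0.5221
    davies_linear_term: float = 0.3
    strict: bool = True

    def __post_init__(self) -> None:
        if self.tol_rel <= 0 or self.tol_mb <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.activity_model not in ("davies", "ideal"):
            raise ValueError(f"unknown activity model {self.activity_model!r}")


@dataclass
class SpeciationResult:
    """Converged free concentrations, activities and diagnostics.

    free_conc is in mmol/L and covers free components, H, and every soluble
    complex; activities are unitless on the molar scale; gamma maps charge
    magnitude -> Davies activity coefficient at the converged ionic strength.
    """

    sample_id: str
    free_conc: dict[str, float]
    activities: dict[str, float]
    gamma: dict[int, float]
    ionic_strength: float
    n_iter: int
    converged: bool
    mb_residuals: dict[str, float]

    def serialize(self) -> str:
        """Deterministic text form (repr of sorted items); used for bitwise
        determinism checks."""
        parts = [
            self.sample_id,
            repr(sorted(self.free_conc.items())),
            repr(sorted(self.activities.items())),
            repr(sorted(self.gamma.items())),
            repr(self.ionic_strength),
            repr(self.n_iter),
            repr(self.converged),
            repr(sorted(self.mb_residuals.items())),
        ]
        return "|".join(parts)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def ionic_strength(conc: Mapping[str, float], charges: Mapping[str, int]) -> float:
    """I = 1/2 * sum_i c_i z_i^2 over every dissolved species, mol/L in, mol/L out."""
    return 0.5 * sum(c * charges[s] ** 2 for s, c in conc.items())


def activity_coefficient(z: int, I: float, opts: SolverOptions = SolverOptions()) -> float:
    """Single-ion activity coefficient.

    Davies model: ``log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - b I)``;
    the ideal model and all neutral species return 1.
    """
    if opts.activity_model == "ideal" or z == 0 or I <= 0.0:
        return 1.0
    sqrt_i = np.sqrt(I)
    log10_gamma = -opts.davies_A * z * z * (sqrt_i / (1.0 + sqrt_i) - opts.davies_linear_term * I)
    # clip guards intermediate non-converged iterates with unphysical I
    return float(10.0 ** np.clip(log10_gamma, -50.0, 50.0))


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _gamma_vector(z: np.ndarray, I: float, opts: SolverOptions) -> np.ndarray:
    if opts.activity_model == "ideal" or I <= 0.0:
        return np.ones_like(z, dtype=float)
    sqrt_i = np.sqrt(I)
    log10_g = -opts.davies_A * z.astype(float) ** 2 * (
        sqrt_i / (1.0 + sqrt_i) - opts.davies_linear_term * I
    )
    return 10.0 ** np.clip(log10_g, -50.0, 50.0)


def _newton_mass_balance(
    T: np.ndarray,
    ln_beta_eff: np.ndarray,
    N: np.ndarray,
    x0: np.ndarray,
    opts: SolverOptions,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Damped Newton on x = ln(free) for fixed activity coefficients.

    ``ln_beta_eff`` already folds in the fixed proton-activity contribution
    and all gamma factors, so ``ln C_k = ln_beta_eff_k + N_k . x``.
    Returns (x, complex_conc, n_iter, converged_inner).
    """
    x = x0.copy()
    max_step = 2.0  # cap on log-space Newton steps; keeps iterates finite
    for it in range(1, opts.max_iter + 1):
        free = np.exp(x)
        C = np.exp(ln_beta_eff + N @ x) if N.size else np.zeros(0)
        resid = free + (N.T @ C if N.size else 0.0) - T
        scale = np.maximum(T, 1e-30)
        rel_resid = np.abs(resid) / scale
        # J_ji = d resid_j / d x_i = delta_ji * free_j + sum_k n_kj n_ki C_k
        J = np.diag(free)
        if N.size:
            J = J + N.T @ (C[:, None] * N)
        try:
            step = np.linalg.solve(J, -resid)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -resid, rcond=None)[0]
        # damp: clamp the log step so concentrations change by < e^2 per iter
        overshoot = np.max(np.abs(step)) if step.size else 0.0
        if overshoot > max_step:
            step = step * (max_step / overshoot)
        x = x + step
        if np.max(np.abs(step), initial=0.0) < opts.tol_rel and np.max(
            rel_resid, initial=0.0
        ) <= opts.tol_mb:
            free = np.exp(x)
            C = np.exp(ln_beta_eff + N @ x) if N.size else np.zeros(0)
            return x, C, it, True
    return x, (np.exp(ln_beta_eff + N @ x) if N.size else np.zeros(0)), opts.max_iter, False


def solve_speciation(
    panel: UrinePanel,
    constants: ConstantsSet,
    opts: SolverOptions = SolverOptions(),
) -> SpeciationResult:
    """Solve the fixed-pH speciation system for one urine sample.

    Returns a :class:`SpeciationResult` whose component mass balances hold to
    ``opts.tol_mb`` (relative) and whose activity coefficients are
    self-consistent with the converged ionic strength.  Deterministic: the
    same inputs produce bitwise-identical results.

    Raises
    ------
    ConvergenceError
        If the iteration budget is exhausted and ``opts.strict`` is set;
        otherwise the result is returned flagged ``converged=False``.
    """
    sp_by_id = constants.species_by_id()
    charges = {s.id: s.charge for s in constants.species}
    a_h = 10.0 ** (-panel.ph)

    # active components: user components with a strictly positive total
    comp_all = constants.component_ids
    # a zero total for an analyte the registry does not track is harmless
    unknown = [a for a, v in panel.totals.items() if a not in sp_by_id and v > 0]
    if unknown:
        raise ValueError(f"sample {panel.sample_id!r}: analytes not in registry: {unknown}")
    totals_mol = {j: panel.totals.get(j, 0.0) / _MMOL_PER_MOL for j in comp_all}
    active = [j for j in comp_all if totals_mol[j] > 0.0]
    idx = {j: i for i, j in enumerate(active)}
    n_c = len(active)
    T = np.array([totals_mol[j] for j in active])
    z_comp = np.array([charges[j] for j in active], dtype=int)

    # active complexes: every non-H reactant must be an active component
    cx_active = [
        c
        for c in constants.complexes
        if all(j == "H" or j in idx for j in c.stoich)
    ]
    n_k = len(cx_active)
    N = np.zeros((n_k, n_c))
    nH = np.zeros(n_k)
    ln_beta = np.zeros(n_k)
    z_cx = np.zeros(n_k, dtype=int)
    ln10 = np.log(10.0)
    for k, c in enumerate(cx_active):
        for j, n in c.stoich.items():
            if j == "H":
                nH[k] = n
            else:
                N[k, idx[j]] = n
        ln_beta[k] = c.log_beta * ln10
        z_cx[k] = c.charge

    # outer fixed point on ionic strength / activity coefficients
    I = 0.0
    gamma_c = np.ones(n_c)
    gamma_k = np.ones(n_k)
    gamma_h = 1.0
    x = np.log(T) if n_c else np.zeros(0)  # start at free = total (dilute limit)
    total_inner = 0
    converged = False
    C = np.zeros(n_k)
    max_outer = 60
    for outer in range(1, max_outer + 1):
        # ln C_k = ln beta_k + nH ln a_H + sum_j n_kj (ln gamma_j + x_j) - ln gamma_k
        ln_beta_eff = (
            ln_beta
            + nH * np.log(a_h)
            + (N @ np.log(gamma_c) if n_c else 0.0)
            - np.log(gamma_k)
        )
        if n_c:
            x, C, it, ok = _newton_mass_balance(T, ln_beta_eff, N, x, opts)
        else:
            C = np.exp(ln_beta_eff)
            it, ok = 1, True
        total_inner += it
        free = np.exp(x) if n_c else np.zeros(0)
        conc_all = {j: free[i] for j, i in idx.items()}
        conc_all["H"] = a_h / gamma_h
        for k, c in enumerate(cx_active):
            conc_all[c.id] = C[k]
        charges_all = dict(charges)
        for c in cx_active:
            charges_all[c.id] = c.charge
        I_new = ionic_strength(conc_all, charges_all)
        dI = abs(I_new - I) / max(I_new, 1e-15)
        I = I_new
        gamma_c = _gamma_vector(z_comp, I, opts) if n_c else gamma_c
        gamma_k = _gamma_vector(z_cx, I, opts) if n_k else gamma_k
        gamma_h = activity_coefficient(1, I, opts)
        # ideal model: gamma never depends on I, one outer pass suffices
        if ok and (dI < 1e-12 or opts.activity_model == "ideal"):
            converged = True
            break

    # assemble result (mmol/L user scale)
    free_conc: dict[str, float] = {}
    activities: dict[str, float] = {}
    mb_residuals: dict[str, float] = {}
    free = np.exp(x) if n_c else np.zeros(0)
    for j in comp_all:
        if j in idx:
            f = float(free[idx[j]])
        else:
            f = 0.0
        free_conc[j] = f * _MMOL_PER_MOL
        gz = activity_coefficient(charges[j], I, opts)
        activities[j] = gz * f
    free_conc["H"] = a_h / gamma_h * _MMOL_PER_MOL
    activities["H"] = a_h
    for k, c in enumerate(cx_active):
        free_conc[c.id] = float(C[k]) * _MMOL_PER_MOL
        activities[c.id] = activity_coefficient(c.charge, I, opts) * float(C[k])
    # residuals on active components
    if n_c:
        bound = N.T @ C if n_k else np.zeros(n_c)
        resid = np.abs(free + bound - T) / np.maximum(T, 1e-30)
        for j, i in idx.items():
            mb_residuals[j] = float(resid[i])
    for j in comp_all:
        mb_residuals.setdefault(j, 0.0)

    zmags = sorted({abs(z) for z in charges.values()} | {abs(int(z)) for z in z_cx})
    gamma_map = {zm: activity_coefficient(zm, I, opts) for zm in zmags}

    result = SpeciationResult(
        sample_id=panel.sample_id,
        free_conc=free_conc,
        activities=activities,
        gamma=gamma_map,
        ionic_strength=float(I),
        n_iter=total_inner,
        converged=converged,
        mb_residuals=mb_residuals,
    )
    if not converged and opts.strict:
        raise ConvergenceError(
            f"sample {panel.sample_id!r}: speciation did not converge in "
            f"{opts.max_iter} inner iterations ({max_outer} outer)"
        )
    return result
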
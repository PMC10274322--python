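"""Independent brute-force speciation oracle for cross-checking the solver.

Solves the same fixed-pH mass-action / mass-balance equations as the package
solver, but through a completely different route: scipy.optimize.root
('hybr', a MINPACK Powell hybrid) on the raw concentration-space residuals,
with activity coefficients iterated by plain fixed point.  Shares no code
with urisat.speciation beyond the registry data structures.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from urisat.constants import ConstantsSet
from urisat.speciation import SolverOptions, UrinePanel


def _davies_gamma(z: int, I: float, opts: SolverOptions) -> float:
    if opts.activity_model == "ideal" or z == 0 or I <= 0:
        return 1.0
    s = np.sqrt(I)
    return 10.0 ** (-opts.davies_A * z * z * (s / (1 + s) - opts.davies_linear_term * I))


def oracle_speciation(
    panel: UrinePanel, constants: ConstantsSet, opts: SolverOptions = SolverOptions()
) -> dict[str, float]:
    """Free concentrations (mol/L) of active components, by brute-force root solve."""
    charges = {s.id: s.charge for s in constants.species}
    a_h = 10.0 ** (-panel.ph)
    totals = {j: panel.totals.get(j, 0.0) / 1000.0 for j in constants.component_ids}
    active = [j for j in constants.component_ids if totals[j] > 0]
    cxs = [c for c in constants.complexes if all(j == "H" or j in active for j in c.stoich)]
    T = np.array([totals[j] for j in active])

    gamma = {j: 1.0 for j in active}
    gamma_cx = {c.id: 1.0 for c in cxs}
    gamma_h = 1.0

    free = T.copy()
    for _ in range(80):  # outer fixed point on ionic strength
        def complex_conc(f: np.ndarray) -> dict[str, float]:
            conc = {}
            for c in cxs:
                a = 10.0 ** c.log_beta
                for j, n in c.stoich.items():
                    if j == "H":
                        a *= a_h ** n
                    else:
                        a *= (gamma[j] * f[active.index(j)]) ** n
                conc[c.id] = a / gamma_cx[c.id]
            return conc

        def residual(f: np.ndarray) -> np.ndarray:
            f = np.abs(f)  # hybr may probe negatives; equations are even-extended
            cc = complex_conc(f)
            r = np.array(
                [
                    f[i]
                    + sum(c.stoich.get(j, 0) * cc[c.id] for c in cxs if j in c.stoich)
                    - T[i]
                    for i, j in enumerate(active)
                ]
            )
            return r / np.maximum(T, 1e-30)

        sol = optimize.root(residual, free, method="hybr", tol=1e-13)
        free = np.abs(sol.x)
        cc = complex_conc(free)
        conc_all = {j: free[i] for i, j in enumerate(active)}
        conc_all["H"] = a_h / gamma_h
        z_all = dict(charges)
        for c in cxs:
            conc_all[c.id] = cc[c.id]
            z_all[c.id] = c.charge
        I = 0.5 * sum(v * z_all[k] ** 2 for k, v in conc_all.items())
        new_gamma = {j: _davies_gamma(charges[j], I, opts) for j in active}
        new_gamma_cx = {c.id: _davies_gamma(c.charge, I, opts) for c in cxs}
        new_gamma_h = _davies_gamma(1, I, opts)
        shift = max(
            [abs(new_gamma[j] - gamma[j]) for j in active]
            + [abs(new_gamma_cx[k] - gamma_cx[k]) for k in gamma_cx]
            + [abs(new_gamma_h - gamma_h)],
            default=0.0,
        )
        gamma, gamma_cx, gamma_h = new_gamma, new_gamma_cx, new_gamma_h
        if shift < 1e-14:
            break
    return {j: float(free[i]) for i, j in enumerate(active)}
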
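"""Speciation solver: elementary operations, closed-form oracles, invariants."""

import math

import numpy as np
import pytest

from urisat.speciation import (
    SolverOptions,
    UrinePanel,
    activity_coefficient,
    ionic_strength,
    solve_speciation,
)

from _oracle import oracle_speciation
from conftest import make_panel, random_small_panel, random_small_registry


class TestIonicStrength:
    def test_one_one_salt(self):
        assert ionic_strength({"Na": 0.1, "Cl": 0.1}, {"Na": 1, "Cl": -1}) == pytest.approx(0.1)

    def test_two_two_salt(self):
        I = ionic_strength({"Ca": 0.001, "Ox": 0.001}, {"Ca": 2, "Ox": -2})
        assert I == pytest.approx(0.004)

    def test_empty_and_zero(self):
        assert ionic_strength({}, {}) == 0.0
        assert ionic_strength({"Na": 0.0}, {"Na": 1}) == 0.0


class TestActivityCoefficient:
    def test_infinite_dilution(self):
        for z in (1, 2, 3):
            assert activity_coefficient(z, 0.0) == 1.0

    def test_ideal_model(self):
        opts = SolverOptions(activity_model="ideal")
        assert activity_coefficient(2, 0.3, opts) == 1.0

    def test_neutral_species(self):
        assert activity_coefficient(0, 0.3) == 1.0

    def test_davies_hand_evaluation(self):
        # direct evaluation of log10 g = -A z^2 (sqrt(I)/(1+sqrt(I)) - b I)
        opts = SolverOptions(davies_A=0.5221, davies_linear_term=0.3)
        I = 0.004
        expected = 10.0 ** (-0.5221 * 4 * (math.sqrt(I) / (1 + math.sqrt(I)) - 0.3 * I))
        assert activity_coefficient(2, I, opts) == pytest.approx(expected, rel=1e-14)

    def test_monotone_approach_to_one(self):
        """Davies gamma rises monotonically toward 1 as I decreases to 0."""
        grid = np.logspace(-1, -12, 30)
        for z in (1, 2, 3):
            g = [activity_coefficient(z, I) for I in grid]
            assert all(b > a for a, b in zip(g, g[1:]))
            assert g[-1] == pytest.approx(1.0, abs=1e-3)
            assert all(0 < v <= 1 for v in g)


class TestPanelValidation:
    def test_ph_bounds(self):
        with pytest.raises(ValueError):
            make_panel(ph=1.5)
        with pytest.warns(UserWarning):
            make_panel(ph=3.5)

    def test_missing_required_analyte(self):
        with pytest.raises(ValueError, match="Ca"):
            UrinePanel(sample_id="x", ph=6.0, totals={"Mg": 1.0})

    def test_negative_total(self):
        with pytest.raises(ValueError, match="negative"):
            make_panel(Ca=-1.0)

    def test_optional_analytes_default_to_zero(self):
        p = UrinePanel(
            sample_id="x",
            ph=6.0,
            totals={a: 1.0 for a in ("Ca", "Mg", "Na", "K", "NH4", "Cl", "SO4", "PO4", "Ox", "Cit")},
        )
        assert p.totals["Ur"] == 0.0 and p.totals["PyroP"] == 0.0


class TestSolver:
    def test_no_complexes_free_equals_total(self, no_complex_registry):
        opts = SolverOptions(activity_model="ideal")
        panel = make_panel(Ca=1.0, Ox=1.0)
        res = solve_speciation(panel, no_complex_registry, opts)
        assert res.converged
        assert res.free_conc["Ca"] == pytest.approx(1.0, rel=1e-12)
        assert res.free_conc["Ox"] == pytest.approx(1.0, rel=1e-12)
        assert res.n_iter == 1

    def test_single_complex_matches_quadratic_solution(self, caox_complex_registry):
        """With one 1:1 complex, mass action + mass balance reduce to a
        quadratic in the free Ca concentration — solve it directly."""
        opts = SolverOptions(activity_model="ideal")
        panel = make_panel(Ca=1.0, Ox=1.0)
        res = solve_speciation(panel, caox_complex_registry, opts)
        K = 10.0 ** 3.19
        T = 1.0e-3  # mol/L; symmetric totals -> free Ca = free Ox = f
        # f + K f^2 = T
        f = (-1.0 + math.sqrt(1.0 + 4.0 * K * T)) / (2.0 * K)
        assert res.free_conc["Ca"] / 1000.0 == pytest.approx(f, rel=1e-9)
        assert res.free_conc["Ox"] / 1000.0 == pytest.approx(f, rel=1e-9)
        assert res.free_conc["CaOx_aq"] / 1000.0 == pytest.approx(K * f * f, rel=1e-9)

    def test_three_component_matches_root_finder(self, three_component_registry):
        panel = make_panel(ph=4.8, Ca=2.0, Ox=1.5)
        res = solve_speciation(panel, three_component_registry)
        oracle = oracle_speciation(panel, three_component_registry)
        for j, f in oracle.items():
            assert res.free_conc[j] / 1000.0 == pytest.approx(f, rel=1e-6), j

    def test_oracle_equivalence_randomized(self):
        """Solver vs independent MINPACK root solve on 100 randomized small
        systems: every free concentration agrees to 1e-6 relative."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            cset = random_small_registry(rng)
            panel = random_small_panel(rng)
            res = solve_speciation(panel, cset)
            oracle = oracle_speciation(panel, cset)
            for j, f in oracle.items():
                assert res.free_conc[j] / 1000.0 == pytest.approx(f, rel=1e-6), (j, cset.name)

    def test_mass_conservation_on_default_registry(self, default_constants):
        rng = np.random.default_rng(7)
        for _ in range(25):
            panel = make_panel(
                ph=float(rng.uniform(5.0, 8.0)),
                Ca=float(rng.uniform(0.2, 8.0)),
                Mg=float(rng.uniform(0.2, 8.0)),
                Na=float(rng.uniform(20, 200)),
                K=float(rng.uniform(20, 150)),
                NH4=float(rng.uniform(5, 80)),
                Cl=float(rng.uniform(30, 250)),
                SO4=float(rng.uniform(2, 40)),
                PO4=float(rng.uniform(5, 80)),
                Ox=float(rng.uniform(0.05, 1.5)),
                Cit=float(rng.uniform(0.1, 8.0)),
            )
            res = solve_speciation(panel, default_constants)
            assert res.converged
            assert max(res.mb_residuals.values()) <= 1e-8

    def test_dilution_limit(self, default_constants):
        """Scaling all totals toward zero drives gamma -> 1 and free/total -> 1."""
        base = dict(
            Ca=2.0, Mg=2.0, Na=80.0, K=60.0, NH4=30.0, Cl=100.0,
            SO4=15.0, PO4=25.0, Ox=0.3, Cit=1.5,
        )
        prev_gamma2 = 0.0
        prev_frac = 0.0
        for s in (1.0, 0.1, 0.01):
            panel = make_panel(ph=6.5, **{k: v * s for k, v in base.items()})
            res = solve_speciation(panel, default_constants)
            frac = res.free_conc["Na"] / panel.totals["Na"]  # Na is nearly fully free
            assert res.gamma[2] > prev_gamma2
            assert frac > prev_frac
            prev_gamma2, prev_frac = res.gamma[2], frac
        # at 100x dilution I is a few mmol/L: gamma2 well on its way to 1,
        # sodium essentially fully free
        assert prev_gamma2 > 0.8
        assert prev_frac > 0.99

    def test_determinism_bitwise(self, default_constants):
        panel = make_panel(ph=6.8, Ca=3.0, Mg=2.0, Na=90.0, K=55.0, NH4=25.0,
                           Cl=120.0, SO4=12.0, PO4=30.0, Ox=0.4, Cit=2.0)
        a = solve_speciation(panel, default_constants).serialize()
        b = solve_speciation(panel, default_constants).serialize()
        assert a == b

    def test_ph_monotonicity_free_phosphate(self, default_constants):
        """Deprotonation: free PO4(3-) activity never decreases as pH rises."""
        base = dict(Ca=2.0, Mg=2.0, Na=80.0, K=60.0, NH4=30.0, Cl=100.0,
                    SO4=15.0, PO4=25.0, Ox=0.3, Cit=1.5)
        acts = []
        for ph in np.linspace(5.0, 8.0, 13):
            res = solve_speciation(make_panel(ph=float(ph), **base), default_constants)
            acts.append(res.activities["PO4"])
        assert all(b >= a for a, b in zip(acts, acts[1:]))

    def test_all_zero_panel(self, default_constants):
        res = solve_speciation(make_panel(ph=7.0), default_constants)
        assert res.converged
        # only water species contribute: I of order 1e-7, gamma ~ 1
        assert 0.0 < res.ionic_strength < 1e-6
        assert res.gamma[1] == pytest.approx(1.0, abs=1e-3)
        for j in ("Ca", "Mg", "Ox"):
            assert res.free_conc[j] == 0.0

    def test_nonconvergence_flagged_not_silent(self, default_constants):
        from urisat.speciation import ConvergenceError

        panel = make_panel(ph=6.5, Ca=2.0, Mg=2.0, Na=80.0, K=60.0, NH4=30.0,
                           Cl=100.0, SO4=15.0, PO4=25.0, Ox=0.3, Cit=1.5)
        tight = SolverOptions(max_iter=1, strict=True)
        with pytest.raises(ConvergenceError, match="s1"):
            solve_speciation(panel, default_constants, tight)
        lax = SolverOptions(max_iter=1, strict=False)
        res = solve_speciation(panel, default_constants, lax)
        assert not res.converged
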
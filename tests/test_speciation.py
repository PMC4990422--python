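"""Equilibrium speciation: closed-form oracles, conservation, reports."""

import numpy as np
import pytest

from thermonet import (
    ConcentrationState,
    ModelError,
    ParameterSet,
    prevalence_report,
    solve_speciation,
    substrate_partition,
    titration_curve,
)
from thermonet.speciation import compile_model


def quadratic_bound(a, x, K):
    s = a + x + K
    return (s - np.sqrt(s * s - 4 * a * x)) / 2


class TestClosedFormOracles:
    def test_hyperbolic_isotherm_at_twice_K(self, toy_binary):
        """Buffered partner at 2K: bound fraction of trace ligand is 2/3."""
        p = ParameterSet({"KR": 1e-7}, {})
        st = ConcentrationState({"P": 2e-7, "R": 1e-9}, buffered=frozenset({"P"}))
        res = solve_speciation(toy_binary, p, st)
        assert res.fractions_by_component["R"]["P-R"] == pytest.approx(2 / 3, abs=1e-8)

    @pytest.mark.parametrize("a,x,K", [
        (3.6e-8, 2e-8, 5e-9),     # tight binding, comparable totals
        (1e-9, 5e-7, 1e-6),       # weak binding, excess ligand
        (1e-6, 1e-6, 1e-12),      # stoichiometric limit
    ])
    def test_quadratic_closed_form(self, toy_binary, a, x, K):
        p = ParameterSet({"KR": K}, {})
        st = ConcentrationState({"P": a, "R": x}, buffered=frozenset())
        res = solve_speciation(toy_binary, p, st)
        expected = quadratic_bound(a, x, K)
        assert res.concentrations["P-R"] == pytest.approx(expected, rel=1e-8)

    def test_hyperbolic_grid(self, toy_binary):
        """Bound fraction tracks x/(x+K) with a buffered titrant."""
        K = 1e-7
        p = ParameterSet({"KR": K}, {})
        for x in np.geomspace(1e-9, 1e-5, 7):
            st = ConcentrationState({"P": x, "R": 1e-12}, buffered=frozenset({"P"}))
            res = solve_speciation(toy_binary, p, st)
            assert res.fractions_by_component["R"]["P-R"] == pytest.approx(
                x / (x + K), rel=1e-8)


class TestConservation:
    def test_mass_balance_random_states(self, model, params, rng):
        for _ in range(20):
            tot = {
                "D": 10 ** rng.uniform(-9, -5), "A": 10 ** rng.uniform(-9, -5),
                "G": 10 ** rng.uniform(-9, -5), "R": 10 ** rng.uniform(-10, -5),
                "T": 10 ** rng.uniform(-6, -2),
            }
            res = solve_speciation(model, params, ConcentrationState(tot))
            assert max(res.residuals.values()) < 1e-9
            for comp, fr in res.fractions_by_component.items():
                assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mass_action_every_reaction(self, model, params):
        st = ConcentrationState({"D": 1e-6, "A": 5e-6, "G": 1e-6, "R": 6e-6, "T": 2.5e-3})
        res = solve_speciation(model, params, st)
        conc = dict(res.concentrations)
        conc["R"], conc["T"] = res.free["R"], res.free["T"]
        Ks = model.reaction_K_half(params)
        for r in model.reactions:
            lig = conc["R"] if r.ligand == "R" else conc["T"] if r.ligand.startswith("T@") else conc[r.ligand]
            assert conc[r.reactant] * lig / conc[r.product] == pytest.approx(
                Ks[r.id], rel=1e-8)

    def test_negative_totals_rejected(self, model, params):
        with pytest.raises(ModelError, match="negative"):
            solve_speciation(model, params, ConcentrationState({"D": -1e-7}))

    def test_brute_force_relaxation_agreement(self, model, params, rng):
        """Damped relaxation from random starts finds the same fixed point."""
        cm = compile_model(model, params)
        for _ in range(3):
            tot = {
                "D": 10 ** rng.uniform(-8, -6), "A": 10 ** rng.uniform(-8, -6),
                "G": 10 ** rng.uniform(-8, -6), "R": 1e-9, "T": 1e-3,
            }
            res = solve_speciation(model, params, ConcentrationState(tot))
            totals = np.array([[tot[c] for c in cm.comp_ids]])
            conserved = np.array([c in ("D", "A", "G") for c in cm.comp_ids])
            cons_idx = np.flatnonzero(conserved)
            lf_buf = np.log(totals.copy())
            lf_buf[:, cons_idx] = 0.0
            buf = (lf_buf @ cm.N.T)[0]
            Nc = cm.N[:, cons_idx]
            target = np.log(totals[0, cons_idx])
            for _start in range(5):
                x = target + rng.uniform(-3, 0, cons_idx.size)
                for _it in range(20000):
                    S = np.exp(cm.lnQ + buf + Nc @ x)
                    F = np.log(S @ Nc) - target
                    if np.abs(F).max() < 1e-12:
                        break
                    x = x - 0.2 * np.clip(F, -20, 20)
                for j, c in enumerate(np.array(cm.comp_ids)[cons_idx]):
                    assert np.exp(x[j]) == pytest.approx(res.free[c], rel=1e-6)


class TestMonotonicity:
    def test_occupancy_monotone_in_constituent_totals(self, toy_square):
        p = ParameterSet({"KR": 1e-6, "KT": 3e-4, "KRT": 1e-4}, {})
        last = -1.0
        for ptot in np.geomspace(1e-8, 1e-4, 8):
            st = ConcentrationState({"P": ptot, "R": 1e-9, "T": 1e-4})
            res = solve_speciation(toy_square, p, st)
            occ = res.concentrations["P-R-TP"]
            assert occ >= last
            last = occ

    def test_substrate_partition_sums_to_one(self, model, params):
        part = substrate_partition(
            model, params, ConcentrationState({"D": 1e-7, "A": 2e-6, "G": 1e-7, "T": 4e-3}))
        assert sum(part.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in part.values())


class TestReports:
    def test_prevalence_rows_sum_to_one(self, model, params):
        states = [ConcentrationState({"D": d, "A": 5e-6, "G": 1e-6, "R": 6e-6, "T": 2.5e-3})
                  for d in (5e-7, 1e-6, 2e-6)]
        rep = prevalence_report(model, params, states, focal="D")
        assert rep.shape[0] == 3
        assert np.allclose(rep.sum(axis=1), 1.0, atol=1e-9)

    def test_oligomer_fraction_monotone_in_ded1p(self, model, params):
        """More total Ded1p pushes more of it into oligomeric states."""
        states = [ConcentrationState({"D": d, "A": 5e-6, "G": 1e-6, "R": 6e-6, "T": 2.5e-3})
                  for d in (5e-7, 1e-6, 2e-6)]
        rep = prevalence_report(model, params, states, focal="D")
        oligo = []
        for st in states:
            res = solve_speciation(model, params, st)
            frac = res.fractions_by_component["D"]
            oligo.append(sum(v for s, v in frac.items()
                             if not s.startswith("free") and
                             model.species_by_id(s).oligomer_state > 1))
        assert oligo[0] < oligo[1] < oligo[2]
        # report agrees with direct speciation for the triple-complex class
        for i, st in enumerate(states):
            res = solve_speciation(model, params, st)
            dag = sum(v for s, v in res.fractions_by_component["D"].items()
                      if not s.startswith("free") and
                      {"A", "G"} <= set(dict(model.species_by_id(s).proteins)))
            assert rep.iloc[i]["+A+G"] == pytest.approx(dag, abs=1e-9)

    def test_prevalence_unknown_focal(self, model, params):
        with pytest.raises(ModelError, match="not a protein"):
            prevalence_report(model, params, [ConcentrationState({"D": 1e-6})], focal="X")

    def test_triple_complex_plurality_at_cellular_state(self, model, params):
        """At ~1 uM Ded1p/eIF4G with excess eIF4A, RNA and ATP, most of both
        proteins resides in the Ded1p-eIF4A-eIF4G complex."""
        st = ConcentrationState({"D": 1e-6, "A": 5e-6, "G": 1e-6, "R": 6e-6, "T": 2.5e-3})
        for focal in ("D", "G"):
            rep = prevalence_report(model, params, [st], focal=focal)
            row = rep.iloc[0]
            assert row["+A+G" if focal == "D" else "+D+A"] == row.max() > 0.5


class TestTitrationCurve:
    def test_half_occupancy_at_K(self, toy_binary):
        p = ParameterSet({"KR": 1e-7}, {})
        fixed = ConcentrationState({"R": 1e-12}, buffered=frozenset({"P"}))
        curve = titration_curve(toy_binary, p, "P", [1e-8, 1e-7, 1e-6], fixed,
                                observable=["P-R"], normalize_by="R")
        assert curve["occupancy"].iloc[1] == pytest.approx(0.5, rel=1e-6)

    def test_empty_grid(self, toy_binary):
        p = ParameterSet({"KR": 1e-7}, {})
        curve = titration_curve(toy_binary, p, "P", [], ConcentrationState({"R": 1e-12}),
                                observable=["P-R"])
        assert curve.empty

    def test_unsorted_grid_rejected(self, toy_binary):
        p = ParameterSet({"KR": 1e-7}, {})
        with pytest.raises(ModelError, match="increasing"):
            titration_curve(toy_binary, p, "P", [1e-6, 1e-7], ConcentrationState({"R": 1e-12}),
                            observable=["P-R"])

    def test_trimer_pathway_is_sigmoidal(self, model, params):
        """Occupancy of the RNA-bound trimer rises cooperatively with Ded1p."""
        from thermonet import fit_hill_isotherm

        grid = np.geomspace(3e-8, 1e-5, 10)
        fixed = ConcentrationState({"R": 1e-12, "T": 4e-3})
        curve = titration_curve(model, params, "D", grid, fixed,
                                observable=["D3-R", "D3-R-TD"], normalize_by="R")
        fit = fit_hill_isotherm(grid, curve["occupancy"].to_numpy())
        assert fit.hill_n > 1.5

    def test_one_to_one_complex_is_hyperbolic(self, model, params):
        """Ded1p-eIF4A binds as a single unit: Hill coefficient near 1."""
        from thermonet import fit_hill_isotherm

        grid = np.geomspace(1e-8, 3e-6, 10)
        fixed = ConcentrationState({"A": 2e-6, "R": 1e-12, "T": 4e-3})
        obs = ["DA-R", "DA-R-TD", "DA-R-TA", "DA-R-TD-TA"]
        curve = titration_curve(model, params, "D", grid, fixed,
                                observable=obs, normalize_by="R")
        fit = fit_hill_isotherm(grid, curve["occupancy"].to_numpy())
        assert 0.9 <= fit.hill_n <= 1.1
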
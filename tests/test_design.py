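from fractions import Fraction

import numpy as np
import pytest

import oracles
from glycodesign import fixtures
from glycodesign.design import (ADP, ATP, INFEASIBLE, NAD, NADH, PI,
                                DesignError, PathwaySolution, SolveOptions,
                                build_design, cofactor_circulation,
                                enumerate_pathways, jaccard,
                                pathway_from_fluxes, solve_minflux,
                                validate_pathway)


class TestBuildDesign:
    def test_proton_coefficient_tracks_atp_yield(self):
        spec = build_design(2, "nadh")
        assert spec.q[ATP] == 2 and spec.q["C00080"] == 2
        assert spec.q[NAD] == -2 and spec.q[NADH] == 2
        assert build_design(4).q["C00080"] == 0

    @pytest.mark.parametrize("bad_n", [0, 6, -1, 2.5])
    def test_yield_outside_theoretical_cap_rejected(self, bad_n):
        with pytest.raises(DesignError):
            build_design(bad_n)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_design_reaction_elementally_balanced(self, n, mini_db):
        # C, O, N, P balance of the overall conversion (H differs by protons)
        spec = build_design(n)
        for el in ("C", "O", "N", "P", "S"):
            net = sum(coeff * mini_db.metabolites[m].formula.get(el, 0)
                      for m, coeff in spec.q.items() if m != "C00080")
            if el == "O":
                net -= 0  # water is part of q, already counted
            assert net == pytest.approx(0.0), (n, el)


class TestMinFlux:
    def test_emp_restriction_recovers_canonical_fluxes(self, mini_db):
        emp = fixtures.named_pathways(mini_db)["emp"]
        sub = fixtures.subset(mini_db, sorted(emp.active_set))
        sol = solve_minflux(sub, build_design(2, "nadh"))
        assert sol is not INFEASIBLE
        assert sol.total_flux == 15
        assert sol.fluxes == emp.fluxes

    def test_disjoint_atp_cycle_blocked_only_by_loop_law(self):
        db, spec = fixtures.toy_loop_db()
        assert solve_minflux(db, spec) is INFEASIBLE
        free = solve_minflux(db, spec, SolveOptions(loopless=False))
        assert free is not INFEASIBLE
        assert {"T03", "T04"} <= free.active_set
        report = validate_pathway(db, free, spec=spec)
        assert not report.checks["no_cofactor_loop"]
        assert cofactor_circulation(db, free) > 0.5

    def test_loopless_constraints_conservative_on_acyclic_network(self):
        db, spec = fixtures.toy_branched_db()
        with_loop = enumerate_pathways(db, spec, max_solutions=10)
        without = enumerate_pathways(
            db, spec, max_solutions=10, opts=SolveOptions(loopless=False))
        assert {p.active_set for p in with_loop} == \
            {p.active_set for p in without}

    def test_solution_satisfies_design_exchange(self, mini_db):
        spec = build_design(1, "either")
        sol = solve_minflux(mini_db, spec)
        assert sol is not INFEASIBLE
        assert validate_pathway(mini_db, sol, spec=spec).ok


class TestEnumeration:
    def test_matches_bruteforce_on_branched_toy(self):
        db, spec = fixtures.toy_branched_db()
        res = enumerate_pathways(db, spec, max_solutions=10)
        assert res.exhaustive
        got = {p.active_set for p in res}
        expected = oracles.bruteforce_pathways(db, spec)
        assert got == expected
        assert len(got) == 3

    def test_matches_bruteforce_on_loop_toy(self):
        db, spec = fixtures.toy_loop_db()
        res = enumerate_pathways(db, spec, max_solutions=10)
        assert res.exhaustive and len(res) == 0
        assert oracles.bruteforce_pathways(db, spec) == set()

    def test_truncation_flagged_non_exhaustive(self):
        db, spec = fixtures.toy_branched_db()
        res = enumerate_pathways(db, spec, max_solutions=2)
        assert len(res) == 2 and not res.exhaustive

    def test_deterministic_and_objective_nondecreasing(self, mini_db):
        spec = build_design(1, "either")
        a = enumerate_pathways(mini_db, spec, max_solutions=4)
        b = enumerate_pathways(mini_db, spec, max_solutions=4)
        assert [p.id for p in a] == [p.id for p in b]
        totals = [p.total_flux for p in a]
        assert totals == sorted(totals)  # cuts only push the optimum up

    def test_solutions_pairwise_distinct(self, mini_db):
        res = enumerate_pathways(mini_db, build_design(1, "either"),
                                 max_solutions=5)
        ps = res.pathways
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                assert jaccard(ps[i], ps[j]) < 1.0


class TestJaccard:
    def test_identical_and_disjoint_and_mixed(self):
        p = lambda *ids: PathwaySolution(fluxes={i: 1.0 for i in ids})
        assert jaccard(p("R1"), p("R1")) == 1.0
        assert jaccard(p("R1"), p("R2")) == 0.0
        assert jaccard(p("R1", "R2", "R3"), p("R2", "R3", "R4")) == 0.5
        assert jaccard(p(), p()) == 1.0


class TestValidatePathway:
    def test_fixture_pathways_pass_all_checks(self, mini_db, pathways):
        for name, p in pathways.items():
            rep = validate_pathway(mini_db, p, spec=fixtures.pathway_design(name))
            assert rep.ok, (name, rep.violations)

    def test_wrong_atp_exchange_fails_design_check(self, mini_db, pathways):
        emp = pathways["emp"]
        rep = validate_pathway(mini_db, emp, spec=build_design(1, "nadh"))
        assert not rep.ok
        assert not rep.checks["design_stoichiometry"]
        assert any(ATP in v for v in rep.violations)

    def test_futile_cycle_fails_circulation_check(self):
        db, spec = fixtures.toy_loop_db()
        p = pathway_from_fluxes(
            db, {"T01": 1, "T02": 1, "T03": 1, "T04": 1},
            exchangeable=set(spec.q))
        rep = validate_pathway(db, p, spec=spec)
        assert not rep.checks["no_cofactor_loop"]
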
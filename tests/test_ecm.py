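import numpy as np
import pytest

import oracles
from glycodesign.design import PathwaySolution
from glycodesign.ecm import (ECMError, KineticAssumptions, cost_vs_mdf,
                             eta_saturation, eta_thermo, minimize_cost)
from glycodesign.mdf import ConcentrationBounds, condition_preset
from glycodesign.reaction_db import RT, Reaction, database_from_dict


def tiny_db(reactions):
    mets = sorted({m for _, s, _ in reactions for m in s})
    return database_from_dict({
        "metabolites": [{"id": m, "formula": {}} for m in mets],
        "cofactors": [],
        "reactions": [{"id": rid, "stoichiometry": s, "dg0_prime": g}
                      for rid, s, g in reactions]})


class TestEfficiencies:
    def test_thermo_efficiency_closed_form(self):
        assert eta_thermo(-RT * np.log(2)) == pytest.approx(0.5)
        assert eta_thermo(-1000.0) == pytest.approx(1.0)
        assert eta_thermo(-1e-6) == pytest.approx(0.0, abs=1e-3)

    def test_thermo_efficiency_rejects_uphill_reactions(self):
        with pytest.raises(ECMError):
            eta_thermo(0.0)
        with pytest.raises(ECMError):
            eta_thermo(4.2)

    def test_saturation_half_at_km(self):
        rxn = Reaction(id="R", stoichiometry={"S": -1, "P": 1})
        got = eta_saturation({"S": 1e-4, "P": 1e-12}, rxn, K_M=1e-4)
        assert got == pytest.approx(0.5, abs=1e-6)

    def test_saturation_approaches_one_when_substrate_saturating(self):
        rxn = Reaction(id="R", stoichiometry={"S": -1, "P": 1})
        high = eta_saturation({"S": 0.1, "P": 1e-6}, rxn, K_M=1e-4)
        assert high == pytest.approx(0.999, abs=2e-3)
        assert eta_saturation({"S": 10.0, "P": 1e-9}, rxn, K_M=1e-4) > 0.999

    def test_saturation_counts_stoichiometry_as_exponents(self):
        rxn = Reaction(id="R", stoichiometry={"S": -2, "P": 1})
        c = {"S": 1e-4, "P": 1e-12}
        # (1)^2 / ((1+1)^2 + 1 - 1) = 1/4
        assert eta_saturation(c, rxn, K_M=1e-4) == pytest.approx(0.25, abs=1e-6)


class TestMinimizeCost:
    def test_single_downhill_reaction_costs_the_baseline(self):
        db = tiny_db([("R1", {"A": -1, "B": 1}, -60.0)])
        p = PathwaySolution(fluxes={"R1": 1.0},
                            exchange_fluxes={"C00031": -1.0})
        res = minimize_cost(p, db, n_restarts=3)
        assert res.total_cost == pytest.approx(0.020, abs=1e-3)
        rc = res.per_reaction["R1"]
        assert rc.thermo_factor == pytest.approx(1.0, abs=1e-3)
        assert rc.saturation_factor == pytest.approx(1.0, abs=5e-3)

    def test_matches_grid_search_oracle_small_pathways(self):
        cases = [
            [("R1", {"A": -1, "B": 1}, -20.0)],
            [("R1", {"A": -1, "B": 1}, -10.0),
             ("R2", {"B": -1, "C": 1}, -8.0)],
        ]
        for reactions in cases:
            db = tiny_db(reactions)
            p = PathwaySolution(fluxes={rid: 1.0 for rid, _, _ in reactions},
                                exchange_fluxes={"C00031": -1.0})
            res = minimize_cost(p, db, n_restarts=4)
            rx = [({m: float(c) for m, c in s.items()}, g)
                  for _, s, g in reactions]
            mets = sorted({m for s, _ in rx for m in s})
            oracle = oracles.ecm_grid_search(
                rx, [1.0] * len(rx), {m: (1e-6, 0.1) for m in mets},
                baseline_mg=0.020, K_M=1e-4)
            assert res.total_cost == pytest.approx(oracle, rel=0.01)

    def test_decomposition_identity_and_floor(self, mini_db, pathways,
                                              fixture_costs):
        for name, res in fixture_costs.items():
            p = pathways[name]
            floor = 0.020 * sum(abs(v) for v in p.fluxes.values())
            assert res.total_cost >= floor - 1e-9, name
            total = 0.0
            for rc in res.per_reaction.values():
                assert rc.cost == pytest.approx(
                    rc.capacity * rc.thermo_factor * rc.saturation_factor,
                    rel=1e-12)
                assert rc.thermo_factor >= 1.0 and rc.saturation_factor >= 1.0
                total += rc.cost
            assert res.total_cost == pytest.approx(total, rel=1e-12)

    def test_emp_costs_more_protein_than_ed(self, fixture_costs):
        assert fixture_costs["emp"].total_cost > fixture_costs["ed"].total_cost

    def test_restarts_agree_on_fixture_pathway(self, mini_db, pathways):
        ref = minimize_cost(pathways["ed"], mini_db, n_restarts=10, seed=1)
        alt = minimize_cost(pathways["ed"], mini_db, n_restarts=10, seed=99)
        assert ref.total_cost == pytest.approx(alt.total_cost, rel=1e-4)

    def test_widening_bounds_never_raises_cost(self, mini_db, pathways):
        wide = minimize_cost(pathways["ed"], mini_db, condition_preset("i"),
                             n_restarts=4)
        tight = minimize_cost(pathways["ed"], mini_db, condition_preset("v"),
                              n_restarts=4)
        assert wide.total_cost <= tight.total_cost * (1 + 1e-6)

    def test_mdf_infeasible_input_gets_infinite_cost(self, mini_db, pathways):
        res = minimize_cost(pathways["sbp_5atp"], mini_db,
                            condition_preset("vi"))
        assert not res.feasible
        assert res.total_cost == np.inf
        assert res.mdf_result is not None and not res.mdf_result.feasible


class TestCostVsMdf:
    def test_cost_strictly_decreasing_in_driving_force(self):
        pathways = []
        dbs = []
        for g in (-5.0, -10.0, -20.0, -40.0):
            db = tiny_db([("R1", {"A": -1, "B": 1}, g)])
            dbs.append(db)
            pathways.append(PathwaySolution(
                fluxes={"R1": 1.0}, exchange_fluxes={"C00031": -1.0}))
        pairs = [cost_vs_mdf([p], db, n_restarts=3)[0]
                 for p, db in zip(pathways, dbs)]
        Bs = [b for b, _ in pairs]
        costs = [c for _, c in pairs]
        assert Bs == sorted(Bs)
        assert costs == sorted(costs, reverse=True)
        assert all(c1 > c2 for c1, c2 in zip(costs, costs[1:]))

    def test_empty_input_gives_empty_output(self, mini_db):
        assert cost_vs_mdf([], mini_db) == []

    def test_kinetic_assumptions_validate(self):
        with pytest.raises(ECMError):
            KineticAssumptions(K_M=-1.0)
        assert KineticAssumptions().baseline_mg == pytest.approx(0.020)
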
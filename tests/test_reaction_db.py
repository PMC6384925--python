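import json
import logging
from fractions import Fraction

import numpy as np
import pytest
import sympy

import oracles
from glycodesign import fixtures
from glycodesign.reaction_db import (RT, Direction, GenericCoefficientError,
                                     Metabolite, RangeUnavailableError,
                                     Reaction, ReactionDatabase,
                                     ValidationError, assign_directionality,
                                     dG_range, database_from_dict,
                                     load_database, parse_equation,
                                     rational_null_basis)

LN1E5 = float(np.log(1e5))


def simple_rxn(dg0, stoich=None):
    return Reaction(id="RX", stoichiometry=stoich or {"A": -1, "B": 1},
                    dg0_prime=dg0)


class TestDGRange:
    @pytest.mark.parametrize("dg0,stoich,expected", [
        (-30.0, {"A": -1, "B": 1}, (-30 - RT * LN1E5, -30 + RT * LN1E5)),
        (0.0, {"A": -1, "B": 1}, (-RT * LN1E5, RT * LN1E5)),
        (0.0, {"A": -1, "B": -1, "C": 1},
         (RT * np.log(1e-6 / 0.01), RT * np.log(0.1 / 1e-12))),
    ])
    def test_closed_forms(self, dg0, stoich, expected):
        lo, hi = dG_range(simple_rxn(dg0, stoich))
        assert lo == pytest.approx(expected[0], abs=1e-9)
        assert hi == pytest.approx(expected[1], abs=1e-9)
        assert lo <= hi

    def test_undefined_dg_signals_unavailable(self):
        with pytest.raises(RangeUnavailableError):
            dG_range(simple_rxn(None))

    def test_width_counts_molecularity_excluding_water_and_protons(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = int(rng.integers(1, 4))
            p = int(rng.integers(1, 4))
            stoich = {f"S{i}": -1 for i in range(s)}
            stoich.update({f"P{i}": 1 for i in range(p)})
            stoich["C00001"] = 1  # water must not widen the range
            lo, hi = dG_range(simple_rxn(float(rng.normal(0, 30)), stoich))
            assert hi - lo == pytest.approx((s + p) * RT * LN1E5, rel=1e-12)


class TestDirectionality:
    def test_forward_when_whole_range_negative(self):
        assert assign_directionality(simple_rxn(-30.0)) is Direction.FORWARD_ONLY

    def test_reverse_when_whole_range_positive(self):
        assert assign_directionality(simple_rxn(30.0)) is Direction.REVERSE_ONLY

    def test_reversible_when_range_straddles_zero(self):
        assert assign_directionality(simple_rxn(0.0)) is Direction.REVERSIBLE

    def test_undefined_energy_means_reversible(self):
        assert assign_directionality(simple_rxn(None)) is Direction.REVERSIBLE

    def test_override_wins_over_rule(self):
        rxn = simple_rxn(0.0)
        got = assign_directionality(rxn, overrides={"RX": Direction.FORWARD_ONLY})
        assert got is Direction.FORWARD_ONLY

    def test_antisymmetric_under_reversal(self):
        flip = {Direction.FORWARD_ONLY: Direction.REVERSE_ONLY,
                Direction.REVERSE_ONLY: Direction.FORWARD_ONLY,
                Direction.REVERSIBLE: Direction.REVERSIBLE}
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_s = int(rng.integers(1, 3))
            n_p = int(rng.integers(1, 3))
            stoich = {f"S{i}": -int(rng.integers(1, 3)) for i in range(n_s)}
            stoich.update({f"P{i}": int(rng.integers(1, 3)) for i in range(n_p)})
            rxn = simple_rxn(float(rng.normal(0, 80)), stoich)
            assert assign_directionality(rxn.reversed()) is \
                flip[assign_directionality(rxn)]


class TestNullBasis:
    def test_two_reaction_cycle_gives_proportional_row(self):
        # A + ATP -> B + ADP ; B -> A, with cofactor rows already removed
        S_red = sympy.Matrix([[-1, 1], [1, -1]])
        N = rational_null_basis(S_red)
        assert N.rows == 1
        assert N[0, 0] == N[0, 1] != 0

    def test_independent_columns_give_empty_basis(self):
        S = sympy.Matrix([[1, 0], [0, 1], [1, 1]])
        assert rational_null_basis(S).rows == 0

    def test_random_integer_matrix_against_exact_rref_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            A = rng.integers(-2, 3, size=(8, 12)).tolist()
            rows = [[Fraction(v) for v in row] for row in A]
            S = sympy.Matrix(A)
            N = rational_null_basis(S)
            oracle = oracles.null_basis_fraction(rows)
            assert N.rows == len(oracle) == 12 - oracles.matrix_rank_fraction(rows)
            # every basis row annihilates S exactly, in rational arithmetic
            prod = S * N.T
            assert prod == sympy.zeros(8, N.rows)
            # spans agree: stacking both bases does not raise the rank
            stacked = [list(map(Fraction, N.row(i))) for i in range(N.rows)]
            stacked += oracle
            if stacked:
                assert oracles.matrix_rank_fraction(stacked) == N.rows

    def test_mini_db_basis_is_exact(self, mini_db):
        prod = mini_db.S_red_exact * mini_db.N_red_exact.T
        assert prod == sympy.zeros(*prod.shape)


class TestLoading:
    def test_mini_db_builds_with_nothing_dropped(self, mini_db, caplog):
        assert mini_db.S.shape == (len(mini_db.metabolites),
                                   len(mini_db.reactions))
        with caplog.at_level(logging.INFO, logger="glycodesign.reaction_db"):
            rebuilt = fixtures.mini_db()
        assert not [r for r in caplog.records if "dropping" in r.message]
        assert rebuilt.reaction_ids == mini_db.reaction_ids

    def test_generic_coefficient_reaction_is_dropped(self, caplog):
        doc = fixtures.mini_db_dict()
        doc["metabolites"] += [
            {"id": c, "formula": {}} for c in ("C00043", "C00167", "C00518",
                                               "C00015")]
        doc["reactions"].append({
            "id": "R05327",
            "stoichiometry": "n C00043 + n C00167 = C00518 + 2n C00015"})
        with caplog.at_level(logging.INFO, logger="glycodesign.reaction_db"):
            db = database_from_dict(doc)
        assert "R05327" not in db
        assert any("R05327" in r.message for r in caplog.records)

    def test_undeclared_metabolite_error_names_reaction(self):
        doc = fixtures.mini_db_dict()
        doc["reactions"].append({"id": "RBAD",
                                 "stoichiometry": {"C99999": -1, "C00022": 1}})
        with pytest.raises(ValidationError, match="RBAD"):
            database_from_dict(doc)

    def test_imbalanced_reaction_is_dropped(self, caplog):
        doc = fixtures.mini_db_dict()
        doc["reactions"].append({  # glucose -> pyruvate loses three carbons
            "id": "RIMB", "stoichiometry": {"C00031": -1, "C00022": 1}})
        with caplog.at_level(logging.INFO, logger="glycodesign.reaction_db"):
            db = database_from_dict(doc)
        assert "RIMB" not in db

    def test_json_file_roundtrip(self, tmp_path, mini_db):
        path = tmp_path / "db.json"
        path.write_text(json.dumps(fixtures.mini_db_dict()))
        db = load_database(path, format="json")
        assert db.reaction_ids == mini_db.reaction_ids
        assert db.reaction("R00299").direction is Direction.FORWARD_ONLY

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            load_database(tmp_path / "nope.json")

    def test_tsv_dialect(self, tmp_path):
        (tmp_path / "db.metabolites.tsv").write_text(
            "id\tname\tformula\tis_cofactor\n"
            "C00031\tglucose\tC6H12O6\tfalse\n"
            "C00022\tpyruvate\tC3H4O3\tfalse\n"
            "C00004\tNADH\tC21H29N7O14P2\ttrue\n"
            "C00003\tNAD+\tC21H28N7O14P2\ttrue\n")
        (tmp_path / "db.tsv").write_text(
            "id\tequation\tdg0_prime\n"
            "RLUMP\tC00031 + 2 C00003 = 2 C00022 + 2 C00004\t-133.6\n")
        db = load_database(tmp_path / "db.tsv", format="table")
        assert db.reaction("RLUMP").stoichiometry["C00022"] == Fraction(2)
        assert db.reaction("RLUMP").dg0_prime == -133.6

    def test_parse_equation_signs(self):
        s = parse_equation("2 A + B = C")
        assert s == {"A": Fraction(-2), "B": Fraction(-1), "C": Fraction(1)}
        with pytest.raises(GenericCoefficientError):
            parse_equation("n A = B")


def test_reaction_invariants():
    with pytest.raises(ValidationError):
        Reaction(id="R0", stoichiometry={})
    r = Reaction(id="R1", stoichiometry={"A": -1, "B": 1})
    assert r.lower_bound == -np.inf and r.upper_bound == np.inf
    r.direction = Direction.FORWARD_ONLY
    assert r.lower_bound == 0.0
    with pytest.raises(ValidationError):
        Metabolite(id="M", formula={"C": -1})
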
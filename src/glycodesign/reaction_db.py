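"""Reaction database: loading, curation, directionality, and exact null bases.

The database holds KEGG-style reactions over KEGG-style compound identifiers.
All stoichiometric coefficients are kept as exact rationals so that the
null-space machinery used by the loop-law constraints holds without any
floating-point tolerance.

Thermodynamic conventions: standard transformed Gibbs energies at pH 7,
25 degC, ionic strength 0.1 M. Water activity is fixed at 1 and protons are
absorbed into the transformed energies, so H2O and H+ never appear in
reaction quotients or concentration variables.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
import sympy

logger = logging.getLogger(__name__)

# --- thermodynamic constants ------------------------------------------------

WATER = "C00001"
PROTON = "C00080"

#: compounds excluded from reaction quotients and concentration variables
QUOTIENT_EXCLUDED = frozenset({WATER, PROTON})


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the transformed-energy convention."""

    R: float = 8.314e-3  # kJ/mol/K
    T: float = 298.15    # K
    pH: float = 7.0
    ionic_strength: float = 0.1  # M

    @property
    def RT(self) -> float:
        return self.R * self.T


THERMO = ThermoConstants()
RT = THERMO.RT  # 2.4789 kJ/mol

#: default freely-interconverted currency metabolites (configurable per DB)
DEFAULT_COFACTORS = frozenset({
    "C00002",  # ATP
    "C00008",  # ADP
    "C00020",  # AMP
    "C00003",  # NAD+
    "C00004",  # NADH
    "C00006",  # NADP+
    "C00005",  # NADPH
    "C00009",  # orthophosphate
    "C00013",  # diphosphate
    "C00001",  # H2O
    "C00080",  # H+
    "C00011",  # CO2
    "C00010",  # CoA
    "C00044",  # GTP
    "C00035",  # GDP
})

BALANCED_ELEMENTS = ("C", "N", "O", "P", "S")  # H allowed to drift by protons


class DatabaseError(Exception):
    """Base class for database problems."""


class ValidationError(DatabaseError):
    """A reaction references an undeclared metabolite or violates a contract."""


class RangeUnavailableError(DatabaseError):
    """dG range requested for a reaction without a defined dG'0."""


class Direction(Enum):
    FORWARD_ONLY = "forward"
    REVERSE_ONLY = "reverse"
    REVERSIBLE = "reversible"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    is_cofactor: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.formula.values()):
            raise ValidationError(f"negative element count in formula of {self.id}")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**6)
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret stoichiometric coefficient {x!r}")


@dataclass
class Reaction:
    """A reaction with signed rational stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, Fraction]
    dg0_prime: float | None = None  # kJ/mol; None = undefined
    direction: Direction = Direction.REVERSIBLE
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id} has empty stoichiometry")
        self.stoichiometry = {m: _as_fraction(c) for m, c in self.stoichiometry.items()
                              if _as_fraction(c) != 0}
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id} has all-zero stoichiometry")

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    @property
    def lower_bound(self) -> float:
        return 0.0 if self.direction is Direction.FORWARD_ONLY else -np.inf

    @property
    def upper_bound(self) -> float:
        return 0.0 if self.direction is Direction.REVERSE_ONLY else np.inf

    def reversed(self) -> "Reaction":
        flip = {Direction.FORWARD_ONLY: Direction.REVERSE_ONLY,
                Direction.REVERSE_ONLY: Direction.FORWARD_ONLY,
                Direction.REVERSIBLE: Direction.REVERSIBLE}
        return Reaction(
            id=self.id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            dg0_prime=None if self.dg0_prime is None else -self.dg0_prime,
            direction=flip[self.direction],
            name=self.name,
        )


# --- directionality ---------------------------------------------------------

def dG_range(rxn: Reaction, c_hi: float = 0.1, c_lo: float = 1e-6,
             constants: ThermoConstants = THERMO) -> tuple[float, float]:
    """Attainable dG' range with every reactant pushed to its extreme.

    dG_min puts all substrates at ``c_hi`` (0.1 M) and all products at
    ``c_lo`` (1 uM); dG_max is the mirror image. Stoichiometric coefficients
    act as exponents in the reaction quotient. H2O and H+ are excluded
    (activity 1 / absorbed at pH 7).
    """
    if rxn.dg0_prime is None:
        raise RangeUnavailableError(f"dG'0 undefined for reaction {rxn.id}")
    rt = constants.RT
    ln_q_min = 0.0
    ln_q_max = 0.0
    for met, coeff in rxn.stoichiometry.items():
        if met in QUOTIENT_EXCLUDED:
            continue
        c = float(coeff)
        if c > 0:  # product
            ln_q_min += c * np.log(c_lo)
            ln_q_max += c * np.log(c_hi)
        else:      # substrate
            ln_q_min += c * np.log(c_hi)
            ln_q_max += c * np.log(c_lo)
    return (rxn.dg0_prime + rt * ln_q_min, rxn.dg0_prime + rt * ln_q_max)


def assign_directionality(rxn: Reaction,
                          overrides: dict[str, Direction] | None = None,
                          c_hi: float = 0.1, c_lo: float = 1e-6) -> Direction:
    """Rule-based direction from the attainable dG' range; overrides win.

    Forward-only iff the whole range is negative, reverse-only iff all
    positive, otherwise reversible. Reactions without a defined dG'0 are
    assumed reversible.
    """
    if overrides and rxn.id in overrides:
        return overrides[rxn.id]
    if rxn.dg0_prime is None:
        return Direction.REVERSIBLE
    lo, hi = dG_range(rxn, c_hi=c_hi, c_lo=c_lo)
    if lo < 0 and hi < 0:
        return Direction.FORWARD_ONLY
    if lo > 0 and hi > 0:
        return Direction.REVERSE_ONLY
    return Direction.REVERSIBLE


# --- exact linear algebra ---------------------------------------------------

def rational_null_basis(S_red: sympy.Matrix) -> sympy.Matrix:
    """Exact rational basis of the null space of ``S_red``.

    Returns a (loops x reactions) matrix whose rows span null(S_red); each
    row is scaled to integer entries. An empty matrix (0 rows) means the
    columns are linearly independent.
    """
    vectors = S_red.nullspace()
    if not vectors:
        return sympy.zeros(0, S_red.shape[1])
    rows = []
    for v in vectors:
        denoms = [sympy.Rational(e).q for e in v]
        scale = sympy.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
        rows.append([sympy.Rational(e) * scale for e in v])
    return sympy.Matrix(rows)


# --- the database container -------------------------------------------------

class ReactionDatabase:
    """Validated reaction set with stoichiometric matrices and loop basis.

    All reactions in the database are internal; exchange fluxes are added by
    the design layer only for design-reaction metabolites and declared
    freely-exchangeable species. ``S_red`` is ``S`` with cofactor rows
    removed, and ``N_red`` is the exact rational null basis of ``S_red``
    whose rows are the cofactor-only loops targeted by the loop law.
    """

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction],
                 cofactors: set[str] | None = None,
                 constants: ThermoConstants = THERMO):
        self.constants = constants
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ValidationError(f"duplicate metabolite id {m.id}")
            self.metabolites[m.id] = m
        if cofactors is None:
            declared = {m.id for m in metabolites if m.is_cofactor}
            cofactors = declared or set(DEFAULT_COFACTORS)
        self.cofactors: set[str] = set(cofactors)
        self.reactions: list[Reaction] = []
        self._index: dict[str, int] = {}
        for r in reactions:
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    raise ValidationError(
                        f"reaction {r.id} references undeclared metabolite {met}")
            if r.id in self._index:
                raise ValidationError(f"duplicate reaction id {r.id}")
            self._index[r.id] = len(self.reactions)
            self.reactions.append(r)
        self._build_matrices()

    # -- access helpers
    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._index[rid]]

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def _build_matrices(self) -> None:
        mets = self.metabolite_ids
        self.met_index = {m: i for i, m in enumerate(mets)}
        n_m, n_r = len(mets), len(self.reactions)
        S = sympy.zeros(n_m, n_r)
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[self.met_index[met], j] = sympy.Rational(coeff.numerator,
                                                           coeff.denominator)
        self.S_exact = S
        self.S = np.array(S.tolist(), dtype=float) if n_m and n_r else np.zeros((n_m, n_r))
        # every reaction in the DB is internal; exchanges live in the design layer
        self.S_int_exact = S
        self.S_int = self.S
        keep = [i for i, m in enumerate(mets) if m not in self.cofactors]
        self.reduced_metabolites = [mets[i] for i in keep]
        self.S_red_exact = S[keep, :] if keep else sympy.zeros(0, n_r)
        self.S_red = self.S[keep, :] if keep else np.zeros((0, n_r))
        self.N_red_exact = rational_null_basis(self.S_red_exact)
        self.N_red = (np.array(self.N_red_exact.tolist(), dtype=float)
                      if self.N_red_exact.rows else np.zeros((0, n_r)))

    # -- curation
    def elemental_imbalance(self, rxn: Reaction) -> dict[str, Fraction]:
        """Net element counts of a reaction over C, N, O, P, S (0 = balanced)."""
        net: dict[str, Fraction] = {e: Fraction(0) for e in BALANCED_ELEMENTS}
        for met, coeff in rxn.stoichiometry.items():
            formula = self.metabolites[met].formula
            for e in BALANCED_ELEMENTS:
                net[e] += coeff * formula.get(e, 0)
        return {e: v for e, v in net.items() if v != 0}


# --- parsing ----------------------------------------------------------------

_COEFF_RE = re.compile(r"^\(?(?P<c>[0-9]+(?:/[0-9]+)?|[0-9]*\.?[0-9]+)?\)?$")


class GenericCoefficientError(DatabaseError):
    """Equation contains a symbolic coefficient such as 'n' or '2n'."""


def parse_equation(text: str) -> dict[str, Fraction]:
    """Parse '2 C00001 + C00002 = C00008 + C00009' into signed coefficients."""
    sides = re.split(r"<?=>?|<->|->", text)
    if len(sides) != 2:
        raise ValidationError(f"equation must have two sides: {text!r}")
    stoich: dict[str, Fraction] = {}

    def add(side: str, sign: int) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                raw = parts[0]
                if re.search(r"[a-mo-zA-Z]", raw) or "n" in raw.lower():
                    raise GenericCoefficientError(
                        f"generic stoichiometric coefficient {raw!r} in {text!r}")
                m = _COEFF_RE.match(raw)
                if not m:
                    raise ValidationError(f"bad coefficient {raw!r} in {text!r}")
                coeff = _as_fraction(raw if "/" in raw else (
                    float(raw) if "." in raw else int(raw)))
                met = parts[1]
            else:
                raise ValidationError(f"cannot parse term {term!r} in {text!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    add(sides[0], -1)
    add(sides[1], +1)
    return {m: c for m, c in stoich.items() if c != 0}


def _curate(metabolites: list[Metabolite], raw_reactions: list[dict],
            cofactors: set[str] | None,
            overrides: dict[str, Direction] | None) -> ReactionDatabase:
    """Drop bad reactions, strip protons, assign directionality, build DB."""
    met_ids = {m.id for m in metabolites}
    kept: list[Reaction] = []
    for entry in raw_reactions:
        rid = entry["id"]
        try:
            stoich = entry["stoichiometry"]
            if isinstance(stoich, str):
                stoich = parse_equation(stoich)
            stoich = {m: _as_fraction(c) for m, c in stoich.items()}
        except GenericCoefficientError as exc:
            logger.info("dropping reaction %s: %s", rid, exc)
            continue
        missing = [m for m in stoich if m not in met_ids]
        if missing:
            raise ValidationError(
                f"reaction {rid} references undeclared metabolite(s) {missing}")
        stoich.pop(PROTON, None)  # absorbed into transformed energies
        if not stoich:
            logger.info("dropping reaction %s: proton-only stoichiometry", rid)
            continue
        rxn = Reaction(id=rid, stoichiometry=stoich,
                       dg0_prime=entry.get("dg0_prime"),
                       name=entry.get("name", ""))
        # standalone balance check so bad reactions never enter the DB
        formulas = {m.id: m.formula for m in metabolites}
        net = {e: sum(c * Fraction(formulas[m].get(e, 0))
                      for m, c in rxn.stoichiometry.items())
               for e in BALANCED_ELEMENTS}
        bad = {e: v for e, v in net.items() if v != 0}
        if bad:
            logger.info("dropping reaction %s: elementally imbalanced %s", rid, bad)
            continue
        rxn.direction = assign_directionality(rxn, overrides=overrides)
        kept.append(rxn)
    return ReactionDatabase(metabolites, kept, cofactors=cofactors)


_DIRECTION_ALIASES = {
    "forward": Direction.FORWARD_ONLY, "forward_only": Direction.FORWARD_ONLY,
    "reverse": Direction.REVERSE_ONLY, "reverse_only": Direction.REVERSE_ONLY,
    "reversible": Direction.REVERSIBLE,
}


def database_from_dict(doc: dict) -> ReactionDatabase:
    """Build a curated database from the documented JSON-schema dict."""
    metabolites = [Metabolite(id=m["id"], name=m.get("name", ""),
                              formula=m.get("formula", {}),
                              is_cofactor=m.get("is_cofactor", False))
                   for m in doc["metabolites"]]
    cof = set(doc["cofactors"]) if "cofactors" in doc else None
    overrides = {rid: _DIRECTION_ALIASES[d.lower()]
                 for rid, d in doc.get("overrides", {}).items()}
    return _curate(metabolites, doc["reactions"], cof, overrides)


def load_database(path: str | Path, format: str = "json") -> ReactionDatabase:
    """Load and curate a reaction database from JSON or TSV.

    JSON schema: an object with ``metabolites`` (id, name, formula,
    is_cofactor), ``reactions`` (id, stoichiometry map or equation string,
    dg0_prime), optional ``cofactors`` (list of ids) and ``overrides``
    (reaction id -> forward|reverse|reversible). The TSV dialect mirrors it:
    a reactions table (columns id, equation, dg0_prime) with sibling files
    ``<stem>.metabolites.tsv`` and optional ``<stem>.overrides.tsv``.

    Elementally imbalanced reactions and reactions with generic symbolic
    coefficients (e.g. 'n') are dropped with a logged reason.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"database file not found: {path}")
    if format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return database_from_dict(doc)
    if format == "table":
        import pandas as pd
        met_path = path.with_suffix(".metabolites.tsv")
        if not met_path.exists():
            raise IOError(f"companion metabolite table not found: {met_path}")
        mdf_ = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
        metabolites = []
        for _, row in mdf_.iterrows():
            formula = {}
            for token in re.findall(r"([A-Z][a-z]?)(\d*)", row.get("formula", "")):
                el, cnt = token
                if el:
                    formula[el] = formula.get(el, 0) + (int(cnt) if cnt else 1)
            metabolites.append(Metabolite(
                id=row["id"], name=row.get("name", ""), formula=formula,
                is_cofactor=str(row.get("is_cofactor", "")).lower()
                in ("1", "true", "yes")))
        rdf = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        raw = [{"id": row["id"], "stoichiometry": row["equation"],
                "dg0_prime": float(row["dg0_prime"]) if row.get("dg0_prime") else None,
                "name": row.get("name", "")} for _, row in rdf.iterrows()]
        overrides = {}
        ov_path = path.with_suffix(".overrides.tsv")
        if ov_path.exists():
            odf = pd.read_csv(ov_path, sep="\t", dtype=str)
            overrides = {row["id"]: _DIRECTION_ALIASES[row["direction"].lower()]
                         for _, row in odf.iterrows()}
        return _curate(metabolites, raw, None, overrides)
    raise ValueError(f"unknown format {format!r} (expected 'json' or 'table')")
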
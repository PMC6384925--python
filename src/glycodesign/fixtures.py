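"""Bundled, download-free test inputs.

The mini reaction database covers canonical EMP and ED glycolysis, the
semi-phosphorylative ED route, the Rapoport-Luebering bypass (including the
2-phosphoglycerate kinase reaction R02664), the non-phosphorylating GAP
dehydrogenase (GAPN), a PPi-dependent phosphofructokinase, and the
sedoheptulose-bisphosphate recycling reactions that enable high-ATP designs.

Thermodynamic data: the bundled standard transformed Gibbs energies are a
SYNTHETIC, internally consistent table. They derive from a single set of
transformed formation energies (pH 7, 25 degC, I = 0.1 M convention)
anchored so that the overall conversions
glucose + 2 NAD(P)+ -> 2 pyruvate + 2 NAD(P)H (-133.6 kJ/mol) and
ADP + Pi -> ATP + H2O (+26.4 kJ/mol) hold exactly, with the remaining
reaction energies set to literature-typical glycolysis values (e.g. the
2-PG kinase R02664 at the -22 kJ/mol midpoint of its attainable range).
Deriving every reaction energy from one formation-energy table makes
pathway energy sums telescope exactly, mirroring how a component-
contribution estimate would behave, but the values are stand-ins, not
estimator output.

KEGG reaction/compound identifiers are reconstructions from standard KEGG
glycolysis entries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (ADP, ATP, CO2, GLUCOSE, NAD, NADH, NADP, NADPH, PI,
                     PYRUVATE, DesignSpec, PathwaySolution, RedoxMode,
                     build_design, pathway_from_fluxes)
from .reaction_db import (WATER, Metabolite, ReactionDatabase,
                          database_from_dict)

PPI = "C00013"

# --- transformed formation energies (kJ/mol), synthetic consistent table ----
# Free anchors (glucose, NAD(P)+, ADP, Pi, H2O at 0) only shift the scale;
# all reaction energies are differences and match literature-typical values.
FORMATION_DG = {
    "C00031": 0.0,      # D-glucose (anchor)
    "C00002": 26.4,     # ATP  (ADP + Pi -> ATP + H2O = +26.4)
    "C00008": 0.0,      # ADP (anchor)
    "C00009": 0.0,      # orthophosphate (anchor)
    "C00013": 19.2,     # diphosphate (PPi hydrolysis -19.2)
    "C00003": 0.0,      # NAD+ (anchor)
    "C00004": -20.0,    # NADH
    "C00006": 0.0,      # NADP+ (anchor)
    "C00005": -20.0,    # NADPH
    "C00001": 0.0,      # H2O (activity 1)
    "C00011": -10.0,    # CO2 (anchor)
    "C00092": 9.4,      # glucose 6-phosphate
    "C00085": 11.9,     # fructose 6-phosphate
    "C00354": 22.2,     # fructose 1,6-bisphosphate
    "C00111": 18.25,    # dihydroxyacetone phosphate
    "C00118": 23.75,    # glyceraldehyde 3-phosphate
    "C00236": 51.25,    # 1,3-bisphosphoglycerate
    "C01159": 14.75,    # 2,3-bisphosphoglycerate
    "C00197": 5.95,     # 3-phosphoglycerate
    "C00631": 10.35,    # 2-phosphoglycerate
    "C00074": 6.35,     # phosphoenolpyruvate
    "C00022": -46.8,    # pyruvate
    "C01236": 26.4,     # 6-phospho-glucono-1,5-lactone
    "C00345": 5.3,      # 6-phosphogluconate
    "C04442": -36.7,    # 2-keto-3-deoxy-6-phosphogluconate (KDPG)
    "C00198": 18.0,     # glucono-1,5-lactone
    "C00257": -3.0,     # gluconate
    "C00204": -43.0,    # 2-keto-3-deoxygluconate (KDG)
    "C00577": 18.8,     # D-glyceraldehyde
    "C00279": 10.0,     # erythrose 4-phosphate (anchor)
    "C05382": -1.05,    # sedoheptulose 7-phosphate
    "C00447": 9.95,     # sedoheptulose 1,7-bisphosphate
    "C00036": -31.4,    # oxaloacetate
}

_FORMULAS = {
    "C00031": "C6H12O6", "C00092": "C6H13O9P", "C00085": "C6H13O9P",
    "C00354": "C6H14O12P2", "C00111": "C3H7O6P", "C00118": "C3H7O6P",
    "C00236": "C3H8O10P2", "C01159": "C3H8O10P2", "C00197": "C3H7O7P",
    "C00631": "C3H7O7P", "C00074": "C3H5O6P", "C00022": "C3H4O3",
    "C01236": "C6H11O9P", "C00345": "C6H13O10P", "C04442": "C6H11O9P",
    "C00198": "C6H10O6", "C00257": "C6H12O7", "C00204": "C6H10O6",
    "C00577": "C3H6O3", "C00279": "C4H9O7P", "C05382": "C7H15O10P",
    "C00447": "C7H16O13P2", "C00036": "C4H4O5",
    "C00002": "C10H16N5O13P3", "C00008": "C10H15N5O10P2",
    "C00009": "H3O4P", "C00013": "H4O7P2",
    "C00003": "C21H28N7O14P2", "C00004": "C21H29N7O14P2",
    "C00006": "C21H28N7O17P3", "C00005": "C21H30N7O17P3",
    "C00001": "H2O", "C00011": "CO2",
}

_NAMES = {
    "C00031": "D-glucose", "C00092": "D-glucose 6-phosphate",
    "C00085": "D-fructose 6-phosphate", "C00354": "D-fructose 1,6-bisphosphate",
    "C00111": "dihydroxyacetone phosphate", "C00118": "D-glyceraldehyde 3-phosphate",
    "C00236": "3-phospho-D-glyceroyl phosphate", "C01159": "2,3-bisphospho-D-glycerate",
    "C00197": "3-phospho-D-glycerate", "C00631": "2-phospho-D-glycerate",
    "C00074": "phosphoenolpyruvate", "C00022": "pyruvate",
    "C01236": "6-phospho-D-glucono-1,5-lactone", "C00345": "6-phospho-D-gluconate",
    "C04442": "2-dehydro-3-deoxy-6-phospho-D-gluconate",
    "C00198": "D-glucono-1,5-lactone", "C00257": "D-gluconate",
    "C00204": "2-dehydro-3-deoxy-D-gluconate", "C00577": "D-glyceraldehyde",
    "C00279": "D-erythrose 4-phosphate", "C05382": "sedoheptulose 7-phosphate",
    "C00447": "sedoheptulose 1,7-bisphosphate", "C00036": "oxaloacetate",
    "C00002": "ATP", "C00008": "ADP", "C00009": "orthophosphate",
    "C00013": "diphosphate", "C00003": "NAD+", "C00004": "NADH",
    "C00006": "NADP+", "C00005": "NADPH", "C00001": "H2O", "C00011": "CO2",
}

_COFACTOR_IDS = {"C00002", "C00008", "C00009", "C00013", "C00003", "C00004",
                 "C00006", "C00005", "C00001", "C00011"}

# (id, name, stoichiometry) written in the canonical glycolytic direction
_MINI_REACTIONS = [
    ("R00299", "hexokinase",
     {"C00031": -1, "C00002": -1, "C00092": 1, "C00008": 1}),
    ("R00771", "glucose-6-phosphate isomerase", {"C00092": -1, "C00085": 1}),
    ("R00756", "6-phosphofructokinase (ATP)",
     {"C00085": -1, "C00002": -1, "C00354": 1, "C00008": 1}),
    ("R00764", "6-phosphofructokinase (PPi)",
     {"C00085": -1, "C00013": -1, "C00354": 1, "C00009": 1}),
    ("R01068", "fructose-bisphosphate aldolase",
     {"C00354": -1, "C00111": 1, "C00118": 1}),
    ("R01015", "triose-phosphate isomerase", {"C00111": -1, "C00118": 1}),
    ("R01061", "GAP dehydrogenase (phosphorylating)",
     {"C00118": -1, "C00009": -1, "C00003": -1, "C00236": 1, "C00004": 1}),
    ("R01512", "phosphoglycerate kinase",
     {"C00236": -1, "C00008": -1, "C00197": 1, "C00002": 1}),
    ("R01518", "phosphoglycerate mutase", {"C00197": -1, "C00631": 1}),
    ("R00658", "enolase", {"C00631": -1, "C00074": 1, "C00001": 1}),
    ("R00200", "pyruvate kinase",
     {"C00074": -1, "C00008": -1, "C00022": 1, "C00002": 1}),
    ("R02736", "glucose-6-phosphate dehydrogenase (NADP+)",
     {"C00092": -1, "C00006": -1, "C01236": 1, "C00005": 1}),
    ("R10907", "glucose-6-phosphate dehydrogenase (NAD+)",
     {"C00092": -1, "C00003": -1, "C01236": 1, "C00004": 1}),
    ("R02035", "6-phosphogluconolactonase",
     {"C01236": -1, "C00001": -1, "C00345": 1}),
    ("R02036", "6-phosphogluconate dehydratase",
     {"C00345": -1, "C04442": 1, "C00001": 1}),
    ("R05605", "KDPG aldolase", {"C04442": -1, "C00022": 1, "C00118": 1}),
    ("R01058", "GAP dehydrogenase (non-phosphorylating, GAPN)",
     {"C00118": -1, "C00006": -1, "C00001": -1, "C00197": 1, "C00005": 1}),
    ("R01662", "bisphosphoglycerate mutase", {"C00236": -1, "C01159": 1}),
    ("R02664", "2-phosphoglycerate kinase",
     {"C00631": -1, "C00002": -1, "C01159": 1, "C00008": 1}),
    ("R01516", "2,3-bisphosphoglycerate phosphatase",
     {"C01159": -1, "C00001": -1, "C00197": 1, "C00009": 1}),
    ("R00305", "glucose 1-dehydrogenase (NAD+)",
     {"C00031": -1, "C00003": -1, "C00198": 1, "C00004": 1}),
    ("R01519", "gluconolactonase", {"C00198": -1, "C00001": -1, "C00257": 1}),
    ("R01538", "gluconate dehydratase", {"C00257": -1, "C00204": 1, "C00001": 1}),
    ("R01541", "KDG kinase",
     {"C00204": -1, "C00002": -1, "C04442": 1, "C00008": 1}),
    ("R01540", "KDG aldolase", {"C00204": -1, "C00022": 1, "C00577": 1}),
    ("R01059", "triokinase",
     {"C00577": -1, "C00002": -1, "C00118": 1, "C00008": 1}),
    ("R01827", "transaldolase",
     {"C00085": -1, "C00279": -1, "C00118": 1, "C05382": 1}),
    ("R01845", "sedoheptulose-bisphosphatase",
     {"C00447": -1, "C00001": -1, "C05382": 1, "C00009": 1}),
    ("R01829", "SBP aldolase (condensation)",
     {"C00111": -1, "C00279": -1, "C00447": 1}),
    ("R00431", "PEP carboxytransphosphorylase",
     {"C00074": -1, "C00011": -1, "C00009": -1, "C00036": 1, "C00013": 1}),
    ("R00344", "pyruvate carboxylase (ATP)",
     {"C00002": -1, "C00022": -1, "C00011": -1, "C00001": -1,
      "C00008": 1, "C00009": 1, "C00036": 1}),
]

#: manually curated directionalities for ATP-coupled kinase steps (the
#: attainable-range rule alone would leave them reversible)
MINI_OVERRIDES = {
    "R00299": "forward",
    "R00756": "forward",
    "R00200": "forward",
    "R01541": "forward",
    "R01059": "forward",
}


class ConnectivityError(Exception):
    pass


def reference_dG(source: str = "bundled") -> dict[str, float]:
    """Standard transformed Gibbs energies for the mini-DB reactions.

    ``bundled`` computes each reaction energy from the frozen synthetic
    formation-energy table (see module docstring). ``external-estimator``
    would re-query a live component-contribution service, which this build
    does not ship.
    """
    if source == "bundled":
        return {rid: round(sum(c * FORMATION_DG[m] for m, c in stoich.items()), 6)
                for rid, _, stoich in _MINI_REACTIONS}
    if source == "external-estimator":
        raise ConnectivityError(
            "no external estimator is bundled; use source='bundled'")
    raise ValueError(f"unknown source {source!r}")


def _parse_formula(text: str) -> dict[str, int]:
    import re
    out: dict[str, int] = {}
    for el, cnt in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if el:
            out[el] = out.get(el, 0) + (int(cnt) if cnt else 1)
    return out


def mini_db_dict() -> dict:
    """The mini database in the documented JSON schema (serializable)."""
    dg = reference_dG("bundled")
    return {
        "metabolites": [
            {"id": cid, "name": _NAMES[cid], "formula": _parse_formula(f),
             "is_cofactor": cid in _COFACTOR_IDS}
            for cid, f in _FORMULAS.items()],
        "cofactors": sorted(_COFACTOR_IDS),
        "reactions": [
            {"id": rid, "name": name,
             "stoichiometry": {m: int(c) for m, c in stoich.items()},
             "dg0_prime": dg[rid]}
            for rid, name, stoich in _MINI_REACTIONS],
        "overrides": dict(MINI_OVERRIDES),
    }


def mini_db() -> ReactionDatabase:
    """Curated mini database (~30 internal reactions, all pathways bundled)."""
    return database_from_dict(mini_db_dict())


def subset(db: ReactionDatabase, reaction_ids) -> ReactionDatabase:
    """Database restricted to the given reaction ids (metabolites pruned)."""
    keep = [db.reaction(r) for r in reaction_ids]
    mets = {m for r in keep for m in r.stoichiometry}
    return ReactionDatabase(
        [db.metabolites[m] for m in db.metabolites if m in mets],
        keep, cofactors=set(db.cofactors))


# --- named fixture pathways -------------------------------------------------

_PATHWAYS: dict[str, tuple[int, str, dict[str, float]]] = {
    # canonical EMP glycolysis: 2 ATP, 2 NADH, total internal flux 15
    "emp": (2, "nadh", {
        "R00299": 1, "R00771": 1, "R00756": 1, "R01068": 1, "R01015": 1,
        "R01061": 2, "R01512": 2, "R01518": 2, "R00658": 2, "R00200": 2}),
    # canonical ED glycolysis: 1 ATP, 1 NADPH + 1 NADH
    "ed": (1, "either", {
        "R00299": 1, "R02736": 1, "R02035": 1, "R02036": 1, "R05605": 1,
        "R01061": 1, "R01512": 1, "R01518": 1, "R00658": 1, "R00200": 1}),
    # semi-phosphorylative ED: phosphorylation deferred to the KDG kinase
    "semi_ed_1atp": (1, "nadh", {
        "R00305": 1, "R01519": 1, "R01538": 1, "R01541": 1, "R05605": 1,
        "R01061": 1, "R01512": 1, "R01518": 1, "R00658": 1, "R00200": 1}),
    # ED-like 1-ATP variant: NAD-dependent G6P dehydrogenase and the
    # Rapoport-Luebering bypass (1,3-BPG -> 2,3-BPG -> 2-PG via R02664)
    "ed_nad_rl_1atp": (1, "nadh", {
        "R00299": 1, "R10907": 1, "R02035": 1, "R02036": 1, "R05605": 1,
        "R01061": 1, "R01662": 1, "R02664": -1, "R00658": 1, "R00200": 1}),
    # ED-like 2-ATP variant: non-phosphorylated upper route to KDG, ATP
    # first invested at glyceraldehyde, recouped thrice downstream
    "ed_like_2atp": (2, "nadh", {
        "R00305": 1, "R01519": 1, "R01538": 1, "R01540": 1, "R01059": 1,
        "R01061": 1, "R01512": 1, "R01516": -1, "R02664": -1,
        "R00658": 1, "R00200": 1}),
    # 3-ATP design: EMP upper, GAP split between GAPDH/PGK and GAPN, both
    # 3-PG routed through the modified Rapoport-Luebering shunt
    "gapn_3atp": (3, "either", {
        "R00299": 1, "R00771": 1, "R00756": 1, "R01068": 1, "R01015": 1,
        "R01061": 1, "R01512": 1, "R01058": 1, "R01516": -2, "R02664": -2,
        "R00658": 2, "R00200": 2}),
    # 4-ATP design: PPi-dependent PFK; PPi recouped via PEP
    # carboxytransphosphorylase and ATP recovered from oxaloacetate
    "ppipfk_4atp": (4, "nadh", {
        "R00299": 1, "R00771": 1, "R00764": 1, "R01068": 1, "R01015": 1,
        "R01061": 2, "R01512": 2, "R01518": 1, "R01516": -1, "R02664": -1,
        "R00658": 2, "R00200": 1, "R00431": 1, "R00344": -1}),
    # 5-ATP design: transaldolase + sedoheptulose-bisphosphate cycle spare
    # the upper ATP investment; both triose branches use the full shunt
    "sbp_5atp": (5, "nadh", {
        "R00299": 1, "R00771": 1, "R01827": 1, "R01845": -1, "R01829": -1,
        "R01015": 1, "R01061": 2, "R01512": 2, "R01516": -2, "R02664": -2,
        "R00658": 2, "R00200": 2}),
}


def named_pathways(db: ReactionDatabase | None = None) -> dict[str, PathwaySolution]:
    """All bundled pathway fixtures keyed by name."""
    db = db or mini_db()
    out = {}
    for name, (n, _, fluxes) in _PATHWAYS.items():
        out[name] = pathway_from_fluxes(db, fluxes, atp_yield=n,
                                        provenance=f"fixture:{name}")
    return out


def pathway_design(name: str) -> DesignSpec:
    """The design reaction a named fixture pathway realizes."""
    n, mode, _ = _PATHWAYS[name]
    return build_design(n, mode)


# --- toy networks -----------------------------------------------------------

def _toy_met(i: int) -> str:
    return f"C999{i:02d}"


def toy_loop_db() -> tuple[ReactionDatabase, DesignSpec]:
    """Tiny network whose only ATP source is a disjoint two-reaction cycle.

    The main chain A -> B -> P moves carbon without touching ATP; a separate
    X/Y cycle nets ADP + Pi -> ATP + H2O (a type II loop). The accompanying
    design demands 1 ATP, so it is satisfiable only by engaging the cycle:
    feasible without loop-law constraints, infeasible with them.
    """
    mets = [Metabolite(id=_toy_met(i), name=f"T{i}",
                       formula={"C": 1, "H": 2, "O": 1}) for i in range(5)]
    cof = [Metabolite(id=c, name=_NAMES[c], formula=_parse_formula(_FORMULAS[c]),
                      is_cofactor=True)
           for c in ("C00002", "C00008", "C00009", "C00001")]
    A, B, P, X, Y = [m.id for m in mets]
    reactions = [
        {"id": "T01", "stoichiometry": {A: -1, B: 1}, "dg0_prime": -20.0},
        {"id": "T02", "stoichiometry": {B: -1, P: 1}, "dg0_prime": -20.0},
        {"id": "T03", "stoichiometry": {X: -1, "C00008": -1, "C00009": -1,
                                        Y: 1, "C00002": 1, "C00001": 1},
         "dg0_prime": -5.0},
        {"id": "T04", "stoichiometry": {Y: -1, X: 1}, "dg0_prime": -5.0},
    ]
    db = database_from_dict({
        "metabolites": [m.__dict__ for m in mets + cof],
        "cofactors": ["C00002", "C00008", "C00009", "C00001"],
        "reactions": reactions})
    spec = DesignSpec(n=1, q={A: -1.0, P: 1.0, ATP: 1.0, ADP: -1.0,
                              PI: -1.0, WATER: 1.0})
    return db, spec


def toy_branched_db() -> tuple[ReactionDatabase, DesignSpec]:
    """Acyclic toy with exactly three source-to-sink routes (A to P).

    Forward-only steps A->B, A->C, B->P, C->P, B->C give the routes
    {AB,BP}, {AC,CP}, {AB,BC,CP}; used to cross-check enumeration against
    brute force.
    """
    mets = [Metabolite(id=_toy_met(10 + i), name=f"N{i}",
                       formula={"C": 1, "H": 2, "O": 1}) for i in range(4)]
    A, B, C, P = [m.id for m in mets]
    reactions = [
        {"id": "T11", "stoichiometry": {A: -1, B: 1}, "dg0_prime": -40.0},
        {"id": "T12", "stoichiometry": {A: -1, C: 1}, "dg0_prime": -40.0},
        {"id": "T13", "stoichiometry": {B: -1, P: 1}, "dg0_prime": -40.0},
        {"id": "T14", "stoichiometry": {C: -1, P: 1}, "dg0_prime": -40.0},
        {"id": "T15", "stoichiometry": {B: -1, C: 1}, "dg0_prime": -40.0},
    ]
    db = database_from_dict({
        "metabolites": [m.__dict__ for m in mets],
        "cofactors": [],
        "reactions": reactions})
    spec = DesignSpec(n=1, q={A: -1.0, P: 1.0})
    return db, spec


@dataclass
class RandomNetwork:
    db: ReactionDatabase
    design: DesignSpec
    loop_members: frozenset[str]   # planted cofactor-cycle reaction ids
    atp_step: str                  # the legitimate ATP-coupled chain step


def random_network(seed: int, n_metabolites: int = 10, n_reactions: int = 12,
                   loop_fraction: float = 0.25) -> RandomNetwork:
    """Seeded random substrate-to-product network with planted ATP cycles.

    A linear carbon chain (one ATP-generating step) converts the substrate
    to the product; ``loop_fraction`` of the reactions are planted as
    closed cofactor-only cycles (each nets ADP + Pi -> ATP + H2O), and any
    remaining budget becomes random reversible shortcuts along the chain.
    Reproducible for a fixed seed; cycle membership is returned as ground
    truth.
    """
    if n_metabolites < 4 or n_reactions < 3:
        raise ValueError("network too small")
    rng = np.random.default_rng(seed)
    n_loop = int(round(loop_fraction * n_reactions))
    cycle_sizes = []
    rem = n_loop
    while rem > 0:
        if rem == 1:
            raise ValueError(
                "loop_fraction leaves a single-reaction cycle; infeasible")
        take = 3 if rem % 2 == 1 else 2
        cycle_sizes.append(take)
        rem -= take
    n_chain_mets = n_metabolites - n_loop
    if n_chain_mets < 2:
        raise ValueError("not enough metabolites for the carbon chain")
    n_chain_rxns = n_chain_mets - 1
    n_extra = n_reactions - n_chain_rxns - n_loop
    if n_extra < 0:
        raise ValueError("n_reactions too small for chain plus planted cycles")

    chain = [_toy_met(i) for i in range(n_chain_mets)]
    mets = [Metabolite(id=m, name=f"M{i}", formula={"C": 1, "H": 2, "O": 1})
            for i, m in enumerate(chain)]
    cof_ids = ("C00002", "C00008", "C00009", "C00001")
    mets += [Metabolite(id=c, name=_NAMES[c],
                        formula=_parse_formula(_FORMULAS[c]), is_cofactor=True)
             for c in cof_ids]
    reactions = []
    atp_idx = int(rng.integers(0, n_chain_rxns))
    atp_step = ""
    for i in range(n_chain_rxns):
        stoich = {chain[i]: -1, chain[i + 1]: 1}
        if i == atp_idx:
            stoich.update({"C00008": -1, "C00009": -1, "C00002": 1, "C00001": 1})
            atp_step = f"RC{i:03d}"
        reactions.append({"id": f"RC{i:03d}", "stoichiometry": stoich,
                          "dg0_prime": float(rng.uniform(-25, -5))})
    loop_members = []
    k = 0
    for s, size in enumerate(cycle_sizes):
        cyc = [_toy_met(50 + k + i) for i in range(size)]
        k += size
        mets += [Metabolite(id=m, name=f"X{s}_{i}",
                            formula={"C": 1, "H": 2, "O": 1})
                 for i, m in enumerate(cyc)]
        for i in range(size):
            stoich = {cyc[i]: -1, cyc[(i + 1) % size]: 1}
            if i == 0:  # the cycle nets ADP + Pi -> ATP + H2O
                stoich.update({"C00008": -1, "C00009": -1,
                               "C00002": 1, "C00001": 1})
            rid = f"RL{s}{i:02d}"
            loop_members.append(rid)
            reactions.append({"id": rid, "stoichiometry": stoich,
                              "dg0_prime": float(rng.uniform(-10, -2))})
    for e in range(n_extra):
        a, b = sorted(rng.choice(n_chain_mets, size=2, replace=False))
        reactions.append({"id": f"RX{e:03d}",
                          "stoichiometry": {chain[a]: -1, chain[b]: 1},
                          "dg0_prime": float(rng.uniform(-15, 5))})
    db = database_from_dict({
        "metabolites": [m.__dict__ for m in mets],
        "cofactors": list(cof_ids),
        "reactions": reactions})
    design = DesignSpec(n=1, q={chain[0]: -1.0, chain[-1]: 1.0, ATP: 1.0,
                                ADP: -1.0, PI: -1.0, WATER: 1.0})
    return RandomNetwork(db=db, design=design,
                         loop_members=frozenset(loop_members),
                         atp_step=atp_step)


# --- headline quantities ----------------------------------------------------

def overall_conversion_dg() -> float:
    """dG'0 of glucose + 2 NAD+ -> 2 pyruvate + 2 NADH (kJ/mol)."""
    g = FORMATION_DG
    return 2 * g[PYRUVATE] + 2 * g[NADH] - g[GLUCOSE] - 2 * g[NAD]


def atp_synthesis_dg() -> float:
    """dG'0 of ADP + Pi -> ATP + H2O (kJ/mol)."""
    g = FORMATION_DG
    return g[ATP] + g[WATER] - g[ADP] - g[PI]


def max_substrate_level_atp_yield() -> float:
    """Largest n with the overall design reaction still exergonic."""
    return -overall_conversion_dg() / atp_synthesis_dg()
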
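"""Readers, writers and DOT visualization.

Pathway JSON schema (canonical for this project):

    {"pathways": [{"id": ..., "atp_yield": n,
                   "reactions": [{"id": "R00299", "flux": 1.0}, ...],
                   "exchanges": [{"metabolite": "C00031", "flux": -1.0}, ...],
                   "provenance": "..."}]}

``read_pathways`` accepts an ``adapter`` hook for foreign dialects so that
dialect drift never touches core logic.
"""
from __future__ import annotations

import json
from pathlib import Path

from .design import ATP, ADP, PathwaySolution
from .mdf import ConcentrationBounds
from .reaction_db import ReactionDatabase


class IOError_(Exception):
    pass


class SchemaError(IOError_):
    pass


# --- pathway JSON -----------------------------------------------------------

def pathway_to_dict(p: PathwaySolution) -> dict:
    return {
        "id": p.id,
        "atp_yield": p.atp_yield,
        "reactions": [{"id": r, "flux": v} for r, v in sorted(p.fluxes.items())],
        "exchanges": [{"metabolite": m, "flux": v}
                      for m, v in sorted(p.exchange_fluxes.items())],
        "provenance": p.provenance,
    }


def pathway_from_dict(doc: dict) -> PathwaySolution:
    for key in ("reactions",):
        if key not in doc:
            raise SchemaError(f"pathway record missing field {key!r}")
    fluxes = {}
    for entry in doc["reactions"]:
        if "id" not in entry or "flux" not in entry:
            raise SchemaError("reaction entry missing field 'id' or 'flux'")
        fluxes[entry["id"]] = float(entry["flux"])
    exchanges = {e["metabolite"]: float(e["flux"])
                 for e in doc.get("exchanges", [])}
    return PathwaySolution(fluxes=fluxes, exchange_fluxes=exchanges,
                           atp_yield=doc.get("atp_yield"),
                           provenance=doc.get("provenance", ""))


def write_pathways(path: str | Path, pathways: list[PathwaySolution]) -> None:
    doc = {"pathways": [pathway_to_dict(p) for p in pathways]}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_pathways(path: str | Path, adapter=None) -> list[PathwaySolution]:
    """Read pathway JSON; ``adapter`` maps a foreign record to the schema."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    records = doc["pathways"] if isinstance(doc, dict) and "pathways" in doc \
        else doc
    if not isinstance(records, list):
        raise SchemaError("expected a list of pathway records")
    if adapter is not None:
        records = [adapter(r) for r in records]
    return [pathway_from_dict(r) for r in records]


# --- bounds files -----------------------------------------------------------

def write_bounds(path: str | Path, bounds: ConcentrationBounds) -> None:
    doc = {"default_lo": bounds.default_lo, "default_hi": bounds.default_hi,
           "per_metabolite": {m: list(v) for m, v in bounds.per_metabolite.items()},
           "ratio_constraints": [list(rc) for rc in bounds.ratio_constraints],
           "fixed": dict(bounds.fixed)}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_bounds(path: str | Path) -> ConcentrationBounds:
    doc = json.loads(Path(path).read_text())
    return ConcentrationBounds(
        default_lo=doc.get("default_lo", 1e-6),
        default_hi=doc.get("default_hi", 0.1),
        per_metabolite={m: tuple(v)
                        for m, v in doc.get("per_metabolite", {}).items()},
        ratio_constraints=tuple(tuple(rc)
                                for rc in doc.get("ratio_constraints", [])),
        fixed=doc.get("fixed", {}))


# --- results table ----------------------------------------------------------

def write_results_tsv(path: str | Path, points) -> None:
    """Write ParetoPoints (or dicts) as a TSV table."""
    import pandas as pd
    rows = []
    for p in points:
        rows.append(p if isinstance(p, dict) else {
            "pathway_id": p.pathway_id, "atp_yield": p.atp_yield,
            "cost": p.cost, "mdf_B": p.mdf_B, "feasible": p.feasible})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- DOT export -------------------------------------------------------------

_HIGHLIGHT = {ATP: "red", ADP: "red"}


def _quote(s: str) -> str:
    return '"' + s.replace('"', r'\"') + '"'


def to_dot(p: PathwaySolution, db: ReactionDatabase) -> str:
    """Directed bipartite pathway graph in DOT.

    Metabolite nodes are ellipses, reaction nodes boxes labeled with the
    reaction id and its flux; edge directions follow flux signs (consumption
    metabolite->reaction, production reaction->metabolite). ATP and ADP are
    highlighted. Output is byte-stable for a fixed input.
    """
    if not p.fluxes:
        raise IOError_("cannot draw an empty pathway")
    mets = set()
    lines = ["digraph pathway {", "  rankdir=TB;",
             "  node [fontsize=10];"]
    edges = []
    for rid in sorted(p.fluxes):
        if rid not in db:
            raise IOError_(f"unknown reaction {rid}")
        v = p.fluxes[rid]
        rnode = f"rxn_{rid}"
        lines.append(f"  {rnode} [shape=box,label="
                     f"{_quote(f'{rid} (v={v:g})')}];")
        for met, coeff in sorted(db.reaction(rid).stoichiometry.items()):
            if met not in db.metabolites:
                raise IOError_(f"unknown metabolite {met}")
            mets.add(met)
            consumed = float(coeff) * v < 0
            if consumed:
                edges.append(f"  met_{met} -> {rnode};")
            else:
                edges.append(f"  {rnode} -> met_{met};")
    for met in sorted(mets):
        name = db.metabolites[met].name or met
        style = ""
        if met in _HIGHLIGHT:
            style = f",color={_HIGHLIGHT[met]},fontcolor={_HIGHLIGHT[met]}"
        shape = "ellipse"
        if db.metabolites[met].is_cofactor:
            shape = "ellipse,style=dashed"
        lines.append(f"  met_{met} [shape={shape},label={_quote(name)}{style}];")
    lines.extend(sorted(edges))
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_dot(path: str | Path, p: PathwaySolution, db: ReactionDatabase) -> None:
    Path(path).write_text(to_dot(p, db))
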
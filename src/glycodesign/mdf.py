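"""Max-min driving force (MDF) thermodynamic feasibility screening.

For a pathway with reactions oriented in their flux direction, the MDF is
the largest B such that some metabolite concentration vector within bounds
makes every reaction's driving force -dG'_j at least B:

    maximize B  s.t.  -(dG'0_j + RT * sum_i S_ij x_i) >= B   for all j,
                      ln(lo_i) <= x_i <= ln(hi_i),
                      ratio constraints on cofactor pairs,

an LP over log-concentrations x. A pathway is thermodynamically operable iff
B > 0. H2O and H+ are excluded from x (activity 1 / pH-7 convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import linprog

from .design import ADP, ATP, PathwaySolution
from .reaction_db import QUOTIENT_EXCLUDED, RT, Reaction, ReactionDatabase


class MDFError(Exception):
    pass


class BoundsRequiredError(MDFError):
    """A named condition needs experimental bound values that were not given."""


class InfeasibleBoundsError(MDFError):
    """The concentration bounds themselves are contradictory (distinct from B <= 0)."""


@dataclass(frozen=True)
class ConcentrationBounds:
    """Concentration intervals (M), cofactor-ratio windows and fixed species."""

    default_lo: float = 1e-6
    default_hi: float = 0.1
    per_metabolite: dict[str, tuple[float, float]] = field(default_factory=dict)
    # (numerator id, denominator id, ratio lo, ratio hi); None = unbounded
    ratio_constraints: tuple[tuple[str, str, float | None, float | None], ...] = ()
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.default_lo <= self.default_hi):
            raise MDFError("need 0 < default_lo <= default_hi")
        for m, (lo, hi) in self.per_metabolite.items():
            if not (0 < lo <= hi):
                raise MDFError(f"bad bounds for {m}: ({lo}, {hi})")

    def interval(self, met: str) -> tuple[float, float]:
        if met in self.fixed:
            return (self.fixed[met], self.fixed[met])
        return self.per_metabolite.get(met, (self.default_lo, self.default_hi))

    def fixing(self, **conc: float) -> "ConcentrationBounds":
        return replace(self, fixed={**self.fixed, **conc})


def condition_preset(name: str,
                     experimental_bounds: dict | None = None) -> ConcentrationBounds:
    """Named concentration-bound presets (i)-(vi).

    (i) all metabolites 1 uM - 100 mM; (v) tightened to 1 uM - 10 mM;
    (vi) layers the ATP/ADP >= 1 ratio constraint on (i). Presets (ii)-(iv)
    are templates for experimentally measured per-metabolite and
    cofactor-ratio windows: their numeric values must be supplied via
    ``experimental_bounds`` (dict with optional keys ``per_metabolite`` and
    ``ratio_constraints``).
    """
    name = name.lower().strip("()")
    if name == "i":
        return ConcentrationBounds()
    if name == "v":
        return ConcentrationBounds(default_hi=0.01)
    if name == "vi":
        return ConcentrationBounds(ratio_constraints=((ATP, ADP, 1.0, None),))
    if name in ("ii", "iii", "iv"):
        if not experimental_bounds:
            raise BoundsRequiredError(
                f"condition ({name}) needs experimentally measured bounds; "
                "pass experimental_bounds={'per_metabolite': ..., "
                "'ratio_constraints': ...}")
        return ConcentrationBounds(
            per_metabolite=dict(experimental_bounds.get("per_metabolite", {})),
            ratio_constraints=tuple(
                tuple(rc) for rc in experimental_bounds.get("ratio_constraints", ())))
    raise MDFError(f"unknown condition preset {name!r}")


@dataclass
class MDFResult:
    B: float
    x: dict[str, float]               # ln concentration at the optimum
    dG_prime: dict[str, float]        # per oriented reaction, kJ/mol
    feasible: bool
    bottleneck: str | None = None

    @property
    def concentrations(self) -> dict[str, float]:
        return {m: float(np.exp(v)) for m, v in self.x.items()}


def oriented_reactions(pathway: PathwaySolution,
                       db: ReactionDatabase) -> list[tuple[Reaction, float]]:
    """Pathway reactions rewritten in their flux direction (with |flux|)."""
    out = []
    for rid, v in sorted(pathway.fluxes.items()):
        r = db.reaction(rid)
        if r.dg0_prime is None:
            raise MDFError(f"reaction {rid} has undefined dG'0")
        out.append((r if v > 0 else r.reversed(), abs(v)))
    return out


def mdf(pathway: PathwaySolution, db: ReactionDatabase,
        bounds: ConcentrationBounds | None = None,
        tol: float = 1e-9) -> MDFResult:
    """Solve the MDF LP for one pathway. ``feasible`` iff B > tol."""
    bounds = bounds or ConcentrationBounds()
    rxns = oriented_reactions(pathway, db)
    if not rxns:
        raise MDFError("empty pathway")
    mets = sorted({m for r, _ in rxns for m in r.stoichiometry}
                  - set(QUOTIENT_EXCLUDED))
    free = [m for m in mets if m not in bounds.fixed]
    idx = {m: i for i, m in enumerate(free)}
    n = len(free)

    # variables: x_0..x_{n-1}, B; minimize -B
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub, b_ub = [], []
    for r, _ in rxns:
        row = np.zeros(n + 1)
        rhs = -r.dg0_prime
        for met, coeff in r.stoichiometry.items():
            if met in QUOTIENT_EXCLUDED:
                continue
            if met in idx:
                row[idx[met]] = RT * float(coeff)
            else:
                rhs -= RT * float(coeff) * np.log(bounds.fixed[met])
        row[-1] = 1.0  # RT*S.x + B <= -dG0
        A_ub.append(row)
        b_ub.append(rhs)
    for num, den, rlo, rhi in bounds.ratio_constraints:
        if num not in idx and den not in idx:
            if num in bounds.fixed and den in bounds.fixed:
                ratio = bounds.fixed[num] / bounds.fixed[den]
                if (rlo is not None and ratio < rlo * (1 - 1e-12)) or \
                        (rhi is not None and ratio > rhi * (1 + 1e-12)):
                    raise InfeasibleBoundsError(
                        f"fixed concentrations violate the {num}/{den} "
                        f"ratio window ({ratio:g} not in [{rlo}, {rhi}])")
            continue
        base = 0.0
        row = np.zeros(n + 1)
        if num in idx:
            row[idx[num]] = 1.0
        else:
            base += np.log(bounds.fixed[num]) if num in bounds.fixed else 0.0
        if den in idx:
            row[idx[den]] = -1.0
        else:
            base -= np.log(bounds.fixed[den]) if den in bounds.fixed else 0.0
        if rhi is not None:
            A_ub.append(row.copy())
            b_ub.append(np.log(rhi) - base)
        if rlo is not None:
            A_ub.append(-row)
            b_ub.append(base - np.log(rlo))

    var_bounds = [tuple(np.log(bounds.interval(m))) for m in free] + [(None, None)]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=var_bounds, method="highs")
    if not res.success:
        raise InfeasibleBoundsError(
            f"concentration bounds are contradictory: {res.message}")
    x = {m: float(res.x[idx[m]]) for m in free}
    x.update({m: float(np.log(v)) for m, v in bounds.fixed.items() if m in mets})
    B = float(-res.fun)
    dg = {}
    for r, _ in rxns:
        g = r.dg0_prime + RT * sum(
            float(cf) * x[m] for m, cf in r.stoichiometry.items()
            if m not in QUOTIENT_EXCLUDED)
        dg[r.id] = float(g)
    bottleneck = max(dg, key=lambda k: dg[k]) if dg else None
    return MDFResult(B=B, x=x, dG_prime=dg, feasible=B > tol,
                     bottleneck=bottleneck)


@dataclass
class ScanResult:
    atp: np.ndarray       # sampled ATP concentrations (M)
    adp: np.ndarray       # sampled ADP concentrations (M)
    B: np.ndarray         # (len(atp), len(adp)) MDF values
    feasible: np.ndarray  # boolean mask
    cost: np.ndarray | None = None  # optional minimal protein cost

    @property
    def n_feasible(self) -> int:
        return int(self.feasible.sum())


def atp_adp_scan(pathway: PathwaySolution, db: ReactionDatabase,
                 bounds: ConcentrationBounds | None = None,
                 grid: tuple[int, int] = (20, 20),
                 conc_range: tuple[float, float] = (1e-6, 0.1),
                 with_cost: bool = False,
                 assumptions=None) -> ScanResult:
    """Re-solve MDF (optionally ECM) on a log-uniform ATP x ADP grid.

    The default 20 x 20 grid samples 400 concentration pairs; for each pair
    ATP and ADP are pinned to the sampled values and all other species keep
    their bounds.
    """
    bounds = bounds or ConcentrationBounds()
    atp_vals = np.logspace(np.log10(conc_range[0]), np.log10(conc_range[1]), grid[0])
    adp_vals = np.logspace(np.log10(conc_range[0]), np.log10(conc_range[1]), grid[1])
    B = np.full(grid, np.nan)
    feas = np.zeros(grid, dtype=bool)
    cost = np.full(grid, np.inf) if with_cost else None
    for i, ca in enumerate(atp_vals):
        for k, cd in enumerate(adp_vals):
            b = bounds.fixing(**{ATP: float(ca), ADP: float(cd)})
            result = mdf(pathway, db, b)
            B[i, k] = result.B
            feas[i, k] = result.feasible
            if with_cost and result.feasible:
                from .ecm import minimize_cost
                ecm_res = minimize_cost(pathway, db, b, assumptions=assumptions)
                cost[i, k] = ecm_res.total_cost
    return ScanResult(atp=atp_vals, adp=adp_vals, B=B, feasible=feas, cost=cost)
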
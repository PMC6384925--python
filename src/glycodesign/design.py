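"""Pathway design: minFlux MILP with cofactor-aware loopless constraints.

The design problem asks for a set of database reactions whose net conversion
equals a prescribed overall "design reaction" (glucose + 2 NAD(P)+ + n ADP +
n Pi -> 2 pyruvate + 2 NAD(P)H + n ATP + n H2O + (4-n) H+) while minimizing
the sum of absolute internal fluxes. Loop-law constraints built on the exact
null basis of the cofactor-reduced stoichiometric matrix forbid closed
subnetworks that exchange only cofactors (futile ATP cycles, redox loops,
water splitting), so ATP formation is forced onto the main carbon chain.

Solved with the HiGHS mixed-integer solver via ``scipy.optimize.milp``.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .reaction_db import Direction, ReactionDatabase, WATER, PROTON

GLUCOSE = "C00031"
PYRUVATE = "C00022"
ATP = "C00002"
ADP = "C00008"
PI = "C00009"
NAD = "C00003"
NADH = "C00004"
NADP = "C00006"
NADPH = "C00005"
CO2 = "C00011"

#: metabolites whose exchange flux is left free rather than fixed by the
#: design reaction (water balances follow from oxygen balance; CO2 may cycle)
DEFAULT_FREE_EXCHANGE = (WATER, CO2)


class RedoxMode(Enum):
    NADH = "nadh"
    NADPH = "nadph"
    EITHER = "either"


class DesignError(Exception):
    pass


class _Infeasible:
    """Distinguished result for an infeasible design problem."""

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "INFEASIBLE"


INFEASIBLE = _Infeasible()


@dataclass(frozen=True)
class DesignSpec:
    """Overall conversion the pathway's exchange fluxes must realize."""

    n: int
    q: dict[str, float]
    redox_mode: RedoxMode = RedoxMode.NADH


def build_design(n: int, redox_mode: RedoxMode | str = RedoxMode.NADH) -> DesignSpec:
    """Design reaction at ATP yield ``n`` (1..5; 5.06 is the theoretical cap).

    glucose + 2 NAD(P)+ + n ADP + n Pi = 2 pyruvate + 2 NAD(P)H + n ATP
    + n H2O + (4-n) H+. In EITHER mode the two redox equivalents may split
    freely between the NADH and NADPH couples.
    """
    if isinstance(redox_mode, str):
        redox_mode = RedoxMode(redox_mode.lower())
    if not (isinstance(n, (int, np.integer)) and 1 <= n <= 5):
        raise DesignError(f"ATP yield n must be an integer in [1, 5], got {n!r}")
    q = {GLUCOSE: -1.0, PYRUVATE: 2.0, ADP: -float(n), PI: -float(n),
         ATP: float(n), WATER: float(n), PROTON: float(4 - n)}
    if redox_mode is RedoxMode.NADH:
        q.update({NAD: -2.0, NADH: 2.0})
    elif redox_mode is RedoxMode.NADPH:
        q.update({NADP: -2.0, NADPH: 2.0})
    # EITHER: redox exchange handled by paired constraints in the MILP
    return DesignSpec(n=int(n), q=q, redox_mode=redox_mode)


@dataclass
class PathwaySolution:
    """Flux vector over active reactions realizing a design reaction."""

    fluxes: dict[str, float]
    exchange_fluxes: dict[str, float] = field(default_factory=dict)
    atp_yield: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.fluxes = {r: float(v) for r, v in self.fluxes.items() if abs(v) > 1e-9}

    @property
    def active_set(self) -> frozenset[str]:
        return frozenset(self.fluxes)

    @property
    def total_flux(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())

    @property
    def id(self) -> str:
        key = ";".join(sorted(self.active_set))
        return hashlib.sha1(key.encode()).hexdigest()[:12]


def pathway_from_fluxes(db: ReactionDatabase, fluxes: dict[str, float],
                        atp_yield: int | None = None,
                        exchangeable: set[str] | None = None,
                        provenance: str = "") -> PathwaySolution:
    """Build a PathwaySolution, deriving exchange fluxes from S.v."""
    if exchangeable is None:
        exchangeable = {GLUCOSE, PYRUVATE, ATP, ADP, PI, NAD, NADH, NADP, NADPH,
                        WATER, CO2}
    net: dict[str, float] = {}
    for rid, v in fluxes.items():
        for met, coeff in db.reaction(rid).stoichiometry.items():
            net[met] = net.get(met, 0.0) + float(coeff) * v
    exchange = {m: x for m, x in net.items()
                if m in exchangeable and abs(x) > 1e-9}
    return PathwaySolution(fluxes=dict(fluxes), exchange_fluxes=exchange,
                           atp_yield=atp_yield, provenance=provenance)


def jaccard(p1: PathwaySolution, p2: PathwaySolution) -> float:
    """Jaccard similarity of the active internal reaction sets."""
    a, b = p1.active_set, p2.active_set
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# --- the MILP ---------------------------------------------------------------

@dataclass
class SolveOptions:
    M: float = 1000.0
    flux_cap: float = 30.0
    integer_fluxes: bool = True
    loopless: bool = True
    activity_eps: float = 1.0  # min |flux| of an active reaction (integer mode)
    free_exchange: tuple[str, ...] = DEFAULT_FREE_EXCHANGE
    time_limit: float | None = None


def _solve_once(db: ReactionDatabase, spec: DesignSpec, opts: SolveOptions,
                cuts: list[frozenset[str]]):
    """One minFlux solve. Returns (fluxes dict, objective) or INFEASIBLE."""
    rxns = db.reactions
    J = len(rxns)
    either = spec.redox_mode is RedoxMode.EITHER
    # variable layout: vf[0:J], vb[J:2J], a[2J:3J], y[3J:4J], G[4J:5J], (z)
    nvar = 5 * J + (1 if either else 0)
    iz = 5 * J
    M = opts.M

    lb = np.zeros(nvar)
    ub = np.zeros(nvar)
    integrality = np.zeros(nvar)
    for j, r in enumerate(rxns):
        ub[j] = M if r.direction is not Direction.REVERSE_ONLY else 0.0
        ub[J + j] = M if r.direction is not Direction.FORWARD_ONLY else 0.0
        ub[2 * J + j] = 1.0
        ub[3 * J + j] = 1.0
        lb[4 * J + j], ub[4 * J + j] = -M, M
        integrality[j] = integrality[J + j] = 1.0 if opts.integer_fluxes else 0.0
        integrality[2 * J + j] = integrality[3 * J + j] = 1.0
    if either:
        lb[iz], ub[iz] = 0.0, 2.0
        integrality[iz] = 1.0 if opts.integer_fluxes else 0.0

    c = np.zeros(nvar)
    c[:2 * J] = 1.0  # minimize sum |v_j|

    rows, cols, vals, con_lb, con_ub = [], [], [], [], []
    nrow = 0

    def add_row(entries, lo, hi):
        nonlocal nrow
        for col, val in entries:
            rows.append(nrow)
            cols.append(col)
            vals.append(val)
        con_lb.append(lo)
        con_ub.append(hi)
        nrow += 1

    # mass balance: S.v = q_i (design), free (skip), 0 (all others)
    fixed_q = dict(spec.q)
    fixed_q.pop(PROTON, None)  # protons absorbed into transformed energies
    redox_pair = {}
    if either:
        fixed_q.pop(NAD, None)
        fixed_q.pop(NADH, None)
        fixed_q.pop(NADP, None)
        fixed_q.pop(NADPH, None)
        redox_pair = {NADH: +1.0, NAD: -1.0}  # S.v = +/- z
    free = set(opts.free_exchange)
    for met, i in db.met_index.items():
        col_entries = [(j, db.S[i, j]) for j in range(J) if db.S[i, j] != 0.0]
        entries = [(j, v) for j, v in col_entries] + \
                  [(J + j, -v) for j, v in col_entries]
        if met in fixed_q:
            add_row(entries, fixed_q[met], fixed_q[met])
        elif either and met in (NADH, NAD):
            add_row(entries + [(iz, -redox_pair[met])], 0.0, 0.0)
        elif either and met in (NADPH, NADP):
            sign = +1.0 if met == NADPH else -1.0
            # S.v = sign * (2 - z)
            add_row(entries + [(iz, sign)], 2.0 * sign if sign > 0 else -2.0,
                    2.0 * sign if sign > 0 else -2.0)
        elif met in free:
            continue  # unconstrained exchange
        else:
            add_row(entries, 0.0, 0.0)

    # loop law on the exact null basis of S_red
    if opts.loopless:
        N = db.N_red
        for l in range(N.shape[0]):
            entries = [(4 * J + j, N[l, j]) for j in range(J) if N[l, j] != 0.0]
            add_row(entries, 0.0, 0.0)
        for j in range(J):
            # 1 - (M+1) a_j <= G_j  and  G_j <= M - (M+1) a_j
            add_row([(4 * J + j, 1.0), (2 * J + j, M + 1.0)], 1.0, np.inf)
            add_row([(4 * J + j, 1.0), (2 * J + j, M + 1.0)], -np.inf, M)

    eps = opts.activity_eps if opts.integer_fluxes else 1e-3
    for j in range(J):
        add_row([(j, 1.0), (2 * J + j, -M)], -np.inf, 0.0)        # vf <= M a
        add_row([(J + j, 1.0), (2 * J + j, M)], -np.inf, M)        # vb <= M(1-a)
        add_row([(j, 1.0), (J + j, 1.0), (3 * J + j, -M)], -np.inf, 0.0)
        add_row([(j, 1.0), (J + j, 1.0), (3 * J + j, -eps)], 0.0, np.inf)

    # total internal flux cap
    add_row([(j, 1.0) for j in range(2 * J)], 0.0, opts.flux_cap)

    # integer cuts: each previously found active set is excluded
    for active in cuts:
        entries = [(3 * J + db._index[rid], 1.0) for rid in active]
        add_row(entries, 0.0, len(active) - 1.0)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, nvar))
    constraints = LinearConstraint(A, np.array(con_lb), np.array(con_ub))
    options = {}
    if opts.time_limit is not None:
        options["time_limit"] = opts.time_limit
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=Bounds(lb, ub), options=options)
    if res.status == 1:  # iteration/time limit
        raise DesignError(f"solver stopped early: {res.message}")
    if not res.success:
        return INFEASIBLE
    x = res.x
    fluxes = {}
    for j, r in enumerate(rxns):
        v = x[j] - x[J + j]
        if opts.integer_fluxes:
            v = round(v)
        if abs(v) > 1e-6:
            fluxes[r.id] = float(v)
    return fluxes, float(res.fun)


def solve_minflux(db: ReactionDatabase, spec: DesignSpec,
                  opts: SolveOptions | None = None,
                  cuts: list[frozenset[str]] | None = None):
    """Minimum-total-flux pathway for a design, or INFEASIBLE.

    Minimizes sum of |v_j| over internal reactions subject to mass balance,
    the design-reaction exchange stoichiometry, directionality bounds, and
    (by default) the cofactor-aware loop-law constraints with big-M 1000.
    """
    opts = opts or SolveOptions()
    out = _solve_once(db, spec, opts, cuts or [])
    if out is INFEASIBLE:
        return INFEASIBLE
    fluxes, _ = out
    return pathway_from_fluxes(
        db, fluxes, atp_yield=spec.n,
        exchangeable=set(spec.q) | set(opts.free_exchange),
        provenance="minflux")


@dataclass
class EnumerationResult:
    pathways: list[PathwaySolution]
    exhaustive: bool

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)


def enumerate_pathways(db: ReactionDatabase, spec: DesignSpec,
                       max_solutions: int = 20,
                       flux_cap: float = 30.0,
                       opts: SolveOptions | None = None) -> EnumerationResult:
    """Enumerate distinct pathways by accumulating integer cuts.

    After each solution with active set A the cut sum_{j in A} y_j <= |A|-1
    is appended; enumeration stops when the MILP turns infeasible
    (exhaustive under the flux cap) or ``max_solutions`` is reached
    (truncated, flagged non-exhaustive). Solutions are pairwise distinct in
    their active sets and each is re-validated post hoc.
    """
    opts = opts or SolveOptions()
    opts.flux_cap = flux_cap
    cuts: list[frozenset[str]] = []
    found: list[PathwaySolution] = []
    exhaustive = False
    while len(found) < max_solutions:
        sol = solve_minflux(db, spec, opts, cuts=cuts)
        if sol is INFEASIBLE:
            exhaustive = True
            break
        report = validate_pathway(db, sol, spec=spec,
                                  free_exchange=opts.free_exchange)
        if not report.ok:
            raise DesignError(
                f"solver returned an invalid pathway {sol.id}: {report.violations}")
        found.append(sol)
        cuts.append(sol.active_set)
    return EnumerationResult(pathways=found, exhaustive=exhaustive)


# --- post-hoc validation ----------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]
    checks: dict[str, bool]


def cofactor_circulation(db: ReactionDatabase, p: PathwaySolution,
                         tol: float = 1e-7) -> float:
    """Max circulation within the active set exchanging only cofactors.

    Auxiliary LP: maximize the summed (direction-aligned) circulation flux w
    with 0 <= sigma_j w_j <= |v_j| and every non-cofactor metabolite strictly
    balanced at zero exchange. A positive optimum exposes a closed
    cofactor-only subnetwork (type II/III loop); loopless solutions attain 0.
    """
    active = sorted(p.active_set)
    if not active:
        return 0.0
    sigma = np.array([np.sign(p.fluxes[r]) for r in active])
    cap = np.array([abs(p.fluxes[r]) for r in active])
    mets = sorted({m for r in active
                   for m in db.reaction(r).stoichiometry} - db.cofactors)
    A = np.zeros((len(mets), len(active)))
    mi = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(active):
        for met, coeff in db.reaction(rid).stoichiometry.items():
            if met in mi:
                A[mi[met], j] = float(coeff)
    # w_j = sigma_j * u_j with u_j in [0, cap_j]
    A_eq = A * sigma
    res = linprog(c=-np.ones(len(active)), A_eq=A_eq,
                  b_eq=np.zeros(len(mets)), bounds=list(zip(np.zeros_like(cap), cap)),
                  method="highs")
    if not res.success:
        raise DesignError(f"auxiliary circulation LP failed: {res.message}")
    return float(-res.fun)


def validate_pathway(db: ReactionDatabase, p: PathwaySolution,
                     spec: DesignSpec | None = None,
                     free_exchange: tuple[str, ...] = DEFAULT_FREE_EXCHANGE,
                     tol: float = 1e-6) -> ValidationReport:
    """Check mass balance, design stoichiometry, bounds and loop-freeness."""
    violations: list[str] = []
    checks: dict[str, bool] = {}

    net: dict[str, float] = {}
    for rid, v in p.fluxes.items():
        if rid not in db:
            violations.append(f"unknown reaction {rid}")
            continue
        r = db.reaction(rid)
        if r.direction is Direction.FORWARD_ONLY and v < -tol:
            violations.append(f"reaction {rid} runs backwards against its bounds")
        if r.direction is Direction.REVERSE_ONLY and v > tol:
            violations.append(f"reaction {rid} runs forwards against its bounds")
        for met, coeff in r.stoichiometry.items():
            net[met] = net.get(met, 0.0) + float(coeff) * v
    checks["bounds"] = not any("against its bounds" in v for v in violations)

    exchangeable = set(free_exchange)
    if spec is not None:
        exchangeable |= set(spec.q)
        if spec.redox_mode is RedoxMode.EITHER:
            exchangeable |= {NAD, NADH, NADP, NADPH}
    else:
        exchangeable |= set(p.exchange_fluxes)

    balance_ok = True
    for met, x in net.items():
        if met not in exchangeable and abs(x) > tol:
            balance_ok = False
            violations.append(f"internal metabolite {met} unbalanced by {x:g}")
    checks["mass_balance"] = balance_ok

    if spec is not None:
        stoich_ok = True
        q = {m: v for m, v in spec.q.items() if m != PROTON}
        if spec.redox_mode is RedoxMode.EITHER:
            for m in (NAD, NADH, NADP, NADPH):
                q.pop(m, None)
            made = net.get(NADH, 0.0) + net.get(NADPH, 0.0)
            if abs(made - 2.0) > tol:
                stoich_ok = False
                violations.append(f"redox production {made:g} != 2")
        for met, want in q.items():
            got = net.get(met, 0.0)
            if abs(got - want) > tol:
                stoich_ok = False
                violations.append(
                    f"exchange of {met} is {got:g}, design requires {want:g}")
        checks["design_stoichiometry"] = stoich_ok

    circ = cofactor_circulation(db, p)
    checks["no_cofactor_loop"] = circ <= 1e-6
    if circ > 1e-6:
        violations.append(
            f"active set admits a cofactor-only circulation of {circ:g}")

    return ValidationReport(ok=not violations, violations=violations, checks=checks)
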
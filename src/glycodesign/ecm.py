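"""Enzyme cost minimization (ECM) under uniform kinetics.

The enzyme demand of a reaction carrying relative flux phi at
log-concentrations x factorizes (separable reversible Michaelis-Menten rate
law combined with the Haldane relationship) as

    cost_j = baseline * phi_j * (1 / eta_rev,j) * (1 / eta_sat,j)

with the thermodynamic efficiency eta_rev = 1 - exp(dG'_j / RT) and the
saturation efficiency eta_sat given by the common-modular rate law. All
enzymes are assumed equally fast with a single Michaelis constant K_M; the
baseline enzyme is 20 ug protein/(mmol Glc/h) per unit relative flux at full
efficiency, and the reference glucose uptake is 1 mmol/gDW/h, so totals come
out in mg protein/mmol glucose/h. The total cost is convex in x, so a
multi-start local solver recovers the global minimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .design import GLUCOSE, PathwaySolution
from .mdf import ConcentrationBounds, MDFResult, mdf, oriented_reactions
from .reaction_db import QUOTIENT_EXCLUDED, RT, Reaction, ReactionDatabase


class ECMError(Exception):
    pass


@dataclass(frozen=True)
class KineticAssumptions:
    """Uniform-kinetics parameters of the protein-cost model."""

    K_M: float = 1e-4                 # M, shared Michaelis constant
    baseline_cost: float = 20.0       # ug protein/(mmol Glc/h) per unit flux
    glucose_flux: float = 1.0         # reference uptake, mmol/gDW/h
    rate_law: str = "CM"              # "CM" (common modular) or "power"

    def __post_init__(self) -> None:
        if self.K_M <= 0 or self.baseline_cost <= 0 or self.glucose_flux <= 0:
            raise ECMError("kinetic parameters must be positive")

    @property
    def baseline_mg(self) -> float:
        return self.baseline_cost / 1000.0


def eta_thermo(dg_prime: float) -> float:
    """Thermodynamic efficiency 1 - exp(dG'/RT), in (0, 1) for dG' < 0."""
    if dg_prime >= 0:
        raise ECMError(
            f"dG' = {dg_prime:g} >= 0: no net forward flux is possible")
    return 1.0 - np.exp(dg_prime / RT)


def eta_saturation(conc: dict[str, float], rxn: Reaction,
                   K_M: float = 1e-4, rate_law: str = "CM") -> float:
    """Fractional enzyme saturation of a reaction at given concentrations.

    Common-modular form over the reaction's substrates s and products p
    (H2O/H+ excluded), with stoichiometric coefficients as exponents:

        eta_sat = prod_s (c_s/K)^m_s /
                  (prod_s (1+c_s/K)^m_s + prod_p (1+c_p/K)^m_p - 1)

    The "power" variant drops the product terms (substrate saturation only).
    """
    num = 1.0
    den_s = 1.0
    den_p = 1.0
    for met, coeff in rxn.stoichiometry.items():
        if met in QUOTIENT_EXCLUDED:
            continue
        m = abs(float(coeff))
        r = conc[met] / K_M
        if coeff < 0:
            num *= r ** m
            den_s *= (1.0 + r) ** m
        else:
            den_p *= (1.0 + r) ** m
    if rate_law == "power":
        return num / den_s
    return num / (den_s + den_p - 1.0)


@dataclass
class ReactionCost:
    capacity: float        # baseline * relative flux, mg
    thermo_factor: float   # 1/eta_rev >= 1
    saturation_factor: float  # 1/eta_sat >= 1
    cost: float            # product of the three, mg/mmol Glc/h


@dataclass
class ECMResult:
    total_cost: float
    per_reaction: dict[str, ReactionCost] = field(default_factory=dict)
    x_opt: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    mdf_result: MDFResult | None = None

    @property
    def feasible(self) -> bool:
        return np.isfinite(self.total_cost)


def _pathway_cost(x: np.ndarray, idx: dict[str, int], fixed_ln: dict[str, float],
                  rxns: list[tuple[Reaction, float]], phi: list[float],
                  assumptions: KineticAssumptions) -> float:
    """Total cost at log-concentrations x; large but finite outside dG'<0."""
    total = 0.0
    for (r, _), f in zip(rxns, phi):
        sx = 0.0
        conc = {}
        for met, coeff in r.stoichiometry.items():
            if met in QUOTIENT_EXCLUDED:
                continue
            lx = x[idx[met]] if met in idx else fixed_ln[met]
            sx += float(coeff) * lx
            conc[met] = np.exp(lx)
        dg = r.dg0_prime + RT * sx
        rev = 1.0 - np.exp(dg / RT)
        if rev <= 1e-12:
            # infeasible point: steep, finite penalty keeps the solver inside
            total += 1e9 * (1.0 + max(dg, 0.0))
            continue
        sat = eta_saturation(conc, r, K_M=assumptions.K_M,
                             rate_law=assumptions.rate_law)
        total += assumptions.baseline_mg * f / (rev * sat)
    return total


def minimize_cost(pathway: PathwaySolution, db: ReactionDatabase,
                  bounds: ConcentrationBounds | None = None,
                  assumptions: KineticAssumptions | None = None,
                  n_restarts: int = 8, seed: int = 0,
                  dg_margin: float = 1e-3, tol: float = 1e-8) -> ECMResult:
    """Minimal protein cost of a pathway over admissible log-concentrations.

    Runs MDF first: an MDF-infeasible pathway gets the distinguished
    infinite-cost result. Otherwise the convex cost is minimized by SLSQP
    from the MDF optimum plus ``n_restarts`` random interior starts, under
    the linear constraints dG'_j <= -dg_margin, the concentration box, and
    any ratio constraints.
    """
    bounds = bounds or ConcentrationBounds()
    assumptions = assumptions or KineticAssumptions()
    mdf_result = mdf(pathway, db, bounds)
    if not mdf_result.feasible:
        return ECMResult(total_cost=np.inf, converged=False,
                         mdf_result=mdf_result)

    rxns = oriented_reactions(pathway, db)
    v_glc = abs(pathway.exchange_fluxes.get(GLUCOSE, 1.0)) or 1.0
    phi = [flux / v_glc for _, flux in rxns]
    mets = sorted({m for r, _ in rxns for m in r.stoichiometry}
                  - set(QUOTIENT_EXCLUDED))
    free = [m for m in mets if m not in bounds.fixed]
    idx = {m: i for i, m in enumerate(free)}
    fixed_ln = {m: float(np.log(v)) for m, v in bounds.fixed.items()}
    n = len(free)
    lo = np.array([np.log(bounds.interval(m)[0]) for m in free])
    hi = np.array([np.log(bounds.interval(m)[1]) for m in free])

    # linear inequality rows: all must be >= 0 at a feasible x
    A_rows, b_rhs = [], []
    for r, _ in rxns:  # -(dG'0 + RT S x) - margin >= 0
        row = np.zeros(n)
        rhs = -r.dg0_prime - dg_margin
        for met, coeff in r.stoichiometry.items():
            if met in QUOTIENT_EXCLUDED:
                continue
            if met in idx:
                row[idx[met]] -= RT * float(coeff)
            else:
                rhs -= RT * float(coeff) * fixed_ln[met]
        A_rows.append(row)
        b_rhs.append(rhs)
    for num, den, rlo, rhi in bounds.ratio_constraints:
        if num not in idx and den not in idx:
            continue
        row = np.zeros(n)
        base = 0.0
        if num in idx:
            row[idx[num]] = 1.0
        elif num in fixed_ln:
            base += fixed_ln[num]
        if den in idx:
            row[idx[den]] = -1.0
        elif den in fixed_ln:
            base -= fixed_ln[den]
        if rlo is not None:  # row.x + base >= ln rlo
            A_rows.append(row.copy())
            b_rhs.append(base - np.log(rlo))
        if rhi is not None:  # ln rhi - row.x - base >= 0
            A_rows.append(-row)
            b_rhs.append(np.log(rhi) - base)
    A = np.array(A_rows)
    b = np.array(b_rhs)

    constraints = [{"type": "ineq", "fun": lambda x: A @ x + b,
                    "jac": lambda x: A}]
    objective = lambda x: _pathway_cost(x, idx, fixed_ln, rxns, phi, assumptions)

    x_mdf = np.clip(np.array([mdf_result.x[m] for m in free]), lo, hi)
    rng = np.random.default_rng(seed)
    starts = [x_mdf]
    for _ in range(n_restarts):
        xr = rng.uniform(lo, hi)
        # pull toward the (strictly feasible) MDF optimum until feasible
        t = 1.0
        for _ in range(40):
            cand = t * xr + (1 - t) * x_mdf
            if np.all(A @ cand + b >= 1e-9):
                break
            t *= 0.7
        starts.append(t * xr + (1 - t) * x_mdf)

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="SLSQP",
                       bounds=list(zip(lo, hi)), constraints=constraints,
                       options={"maxiter": 400, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    x_opt = np.clip(best.x, lo, hi)

    per_reaction: dict[str, ReactionCost] = {}
    total = 0.0
    for (r, _), f in zip(rxns, phi):
        sx = 0.0
        conc = {}
        for met, coeff in r.stoichiometry.items():
            if met in QUOTIENT_EXCLUDED:
                continue
            lx = x_opt[idx[met]] if met in idx else fixed_ln[met]
            sx += float(coeff) * lx
            conc[met] = np.exp(lx)
        dg = r.dg0_prime + RT * sx
        rev = eta_thermo(min(dg, -1e-12))
        sat = eta_saturation(conc, r, K_M=assumptions.K_M,
                             rate_law=assumptions.rate_law)
        cost = assumptions.baseline_mg * f / (rev * sat)
        per_reaction[r.id] = ReactionCost(
            capacity=assumptions.baseline_mg * f,
            thermo_factor=1.0 / rev, saturation_factor=1.0 / sat, cost=cost)
        total += cost
    x_map = {m: float(x_opt[i]) for m, i in idx.items()}
    x_map.update({m: v for m, v in fixed_ln.items() if m in mets})
    return ECMResult(total_cost=float(total), per_reaction=per_reaction,
                     x_opt=x_map, converged=bool(best.success),
                     mdf_result=mdf_result)


def cost_vs_mdf(pathways: list[PathwaySolution], db: ReactionDatabase,
                bounds: ConcentrationBounds | None = None,
                assumptions: KineticAssumptions | None = None,
                **kwargs) -> list[tuple[float, float]]:
    """(MDF B, minimal cost) pairs for a family of pathways."""
    out = []
    for p in pathways:
        res = minimize_cost(p, db, bounds, assumptions=assumptions, **kwargs)
        B = res.mdf_result.B if res.mdf_result is not None else np.nan
        out.append((float(B), float(res.total_cost)))
    return out
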
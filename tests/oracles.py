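"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact Gaussian
elimination over Fractions for null spaces, refined grid search for the MDF
and ECM optima, and exhaustive integer flux enumeration for pathway counts.
"""
from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

from glycodesign.reaction_db import QUOTIENT_EXCLUDED, RT


# --- exact linear algebra ----------------------------------------------------

def rref_fraction(rows: list[list[Fraction]]):
    """Reduced row echelon form with exact Fraction arithmetic."""
    m = [list(map(Fraction, r)) for r in rows]
    nrow = len(m)
    ncol = len(m[0]) if nrow else 0
    pivots = []
    r = 0
    for c in range(ncol):
        pivot = next((i for i in range(r, nrow) if m[i][c] != 0), None)
        if pivot is None:
            continue
        m[r], m[pivot] = m[pivot], m[r]
        inv = m[r][c]
        m[r] = [v / inv for v in m[r]]
        for i in range(nrow):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == nrow:
            break
    return m, pivots


def null_basis_fraction(rows: list[list[Fraction]]) -> list[list[Fraction]]:
    """Null-space basis from exact RREF (one vector per free column)."""
    m, pivots = rref_fraction(rows)
    ncol = len(rows[0]) if rows else 0
    free = [c for c in range(ncol) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * ncol
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -m[r][fc]
        basis.append(v)
    return basis


def matrix_rank_fraction(rows) -> int:
    return len(rref_fraction(rows)[1])


# --- MDF grid-search oracle --------------------------------------------------

def mdf_grid_search(rxns, met_bounds: dict[str, tuple[float, float]],
                    n_points: int = 15, refinements: int = 6) -> float:
    """Max-min driving force by refined exhaustive grid search.

    ``rxns`` is a list of (stoichiometry dict, dg0) oriented in flux
    direction; ``met_bounds`` maps metabolite -> (lo, hi) in M. Searches
    ln-concentration space on a full grid, then repeatedly zooms on the
    incumbent. Only practical for <= 4 metabolites.
    """
    mets = sorted({m for s, _ in rxns for m in s} - set(QUOTIENT_EXCLUDED))
    lo = np.array([np.log(met_bounds[m][0]) for m in mets])
    hi = np.array([np.log(met_bounds[m][1]) for m in mets])
    coeff = np.array([[float(s.get(m, 0)) for m in mets] for s, _ in rxns])
    dg0 = np.array([g for _, g in rxns])

    best_x, best = None, -np.inf
    cur_lo, cur_hi = lo.copy(), hi.copy()
    for _ in range(refinements):
        axes = [np.linspace(a, b, n_points) for a, b in zip(cur_lo, cur_hi)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        pts = grid.reshape(-1, len(mets))
        driving = -(dg0[None, :] + RT * pts @ coeff.T)
        score = driving.min(axis=1)
        k = int(score.argmax())
        if score[k] > best:
            best, best_x = float(score[k]), pts[k]
        width = (cur_hi - cur_lo) / (n_points - 1) * 2.0
        cur_lo = np.maximum(lo, best_x - width)
        cur_hi = np.minimum(hi, best_x + width)
    return best


# --- ECM grid-search oracle --------------------------------------------------

def ecm_grid_search(rxns, phi, met_bounds, baseline_mg: float, K_M: float,
                    n_points: int = 15, refinements: int = 6) -> float:
    """Minimal total enzyme cost by refined grid search (<= 3 metabolites)."""
    mets = sorted({m for s, _ in rxns for m in s} - set(QUOTIENT_EXCLUDED))
    lo = np.array([np.log(met_bounds[m][0]) for m in mets])
    hi = np.array([np.log(met_bounds[m][1]) for m in mets])

    def total_cost(pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[0])
        for (stoich, dg0), f in zip(rxns, phi):
            sx = np.zeros(pts.shape[0])
            num = np.ones(pts.shape[0])
            den_s = np.ones(pts.shape[0])
            den_p = np.ones(pts.shape[0])
            for m, c in stoich.items():
                if m in QUOTIENT_EXCLUDED:
                    continue
                x = pts[:, mets.index(m)]
                sx += float(c) * x
                r = np.exp(x) / K_M
                if c < 0:
                    num *= r ** abs(float(c))
                    den_s *= (1 + r) ** abs(float(c))
                else:
                    den_p *= (1 + r) ** abs(float(c))
            dg = dg0 + RT * sx
            rev = 1.0 - np.exp(dg / RT)
            sat = num / (den_s + den_p - 1.0)
            bad = rev <= 0
            rev = np.where(bad, 1.0, rev)
            contrib = baseline_mg * f / (rev * sat)
            out += np.where(bad, np.inf, contrib)
        return out

    best_x, best = None, np.inf
    cur_lo, cur_hi = lo.copy(), hi.copy()
    for _ in range(refinements):
        axes = [np.linspace(a, b, n_points) for a, b in zip(cur_lo, cur_hi)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        pts = pts.reshape(-1, len(mets))
        val = total_cost(pts)
        k = int(val.argmin())
        if val[k] < best:
            best, best_x = float(val[k]), pts[k]
        width = (cur_hi - cur_lo) / (n_points - 1) * 2.0
        cur_lo = np.maximum(lo, best_x - width)
        cur_hi = np.minimum(hi, best_x + width)
    return best


# --- exhaustive pathway enumeration ------------------------------------------

def bruteforce_pathways(db, spec, free_exchange=(), max_flux: int = 3,
                        flux_cap: float = 30.0) -> set[frozenset[str]]:
    """All active sets of integer flux vectors satisfying a design.

    Enumerates every flux assignment with |v_j| <= max_flux (respecting
    directionality), keeps those that balance internal metabolites, hit the
    design exchange stoichiometry, stay under the flux cap, and admit no
    cofactor-only circulation within their active set. Only for tiny
    databases (<= 12 reactions).
    """
    from glycodesign.design import (PROTON, PathwaySolution,
                                    cofactor_circulation)
    rxns = db.reactions
    assert len(rxns) <= 12
    q = {m: v for m, v in spec.q.items() if m != PROTON}
    free = set(free_exchange)
    choices = []
    for r in rxns:
        lo = 0 if r.lower_bound == 0 else -max_flux
        hi = 0 if r.upper_bound == 0 else max_flux
        choices.append(range(lo, hi + 1))
    found: set[frozenset[str]] = set()
    for combo in itertools.product(*choices):
        if sum(abs(v) for v in combo) > flux_cap or not any(combo):
            continue
        net: dict[str, float] = {}
        for r, v in zip(rxns, combo):
            if v:
                for m, c in r.stoichiometry.items():
                    net[m] = net.get(m, 0) + float(c) * v
        ok = True
        for m in set(net) | set(q):
            want = q.get(m)
            got = net.get(m, 0.0)
            if want is not None:
                ok = abs(got - want) < 1e-9
            elif m in free:
                ok = True
            else:
                ok = abs(got) < 1e-9
            if not ok:
                break
        if not ok:
            continue
        active = frozenset(r.id for r, v in zip(rxns, combo) if v)
        if active in found:
            continue
        p = PathwaySolution(fluxes={r.id: float(v)
                                    for r, v in zip(rxns, combo) if v})
        if cofactor_circulation(db, p) <= 1e-6:
            found.add(active)
    return found
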
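"""Pareto analysis of the ATP-yield vs. protein-cost tradeoff."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ParetoError(Exception):
    pass


@dataclass(frozen=True)
class ParetoPoint:
    pathway_id: str
    atp_yield: float          # mol ATP / mol glucose
    cost: float               # mg protein / mmol Glc / h
    mdf_B: float = np.nan     # kJ/mol
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.feasible and not self.cost > 0:
            raise ParetoError(
                f"feasible point {self.pathway_id} must have positive cost")


def pareto_front(points: list[ParetoPoint]) -> list[tuple[float, float]]:
    """Per-yield minimum-cost vertices, ordered by yield.

    The front is the piecewise-linear curve through one (yield, min cost)
    vertex per represented ATP yield; only feasible points participate. No
    monotonicity of cost in yield is assumed.
    """
    feas = [p for p in points if p.feasible and np.isfinite(p.cost)]
    if not feas:
        raise ParetoError("no feasible points: cannot build a Pareto front")
    best: dict[float, float] = {}
    for p in feas:
        best[p.atp_yield] = min(best.get(p.atp_yield, np.inf), p.cost)
    return sorted(best.items())


def front_members(points: list[ParetoPoint],
                  rel_tol: float = 1e-9) -> list[ParetoPoint]:
    """All points attaining the per-yield minimum (ties all flagged)."""
    front = dict(pareto_front(points))
    return [p for p in points
            if p.feasible and np.isfinite(p.cost)
            and p.cost <= front[p.atp_yield] * (1 + rel_tol)]


def distance_to_front(p: ParetoPoint,
                      front: list[tuple[float, float]]) -> float:
    """Cost-axis distance from a point to the front at its own yield.

    Measured in mg protein/mmol Glc/h at fixed yield; zero for front
    members. Raises if the point's yield has no front vertex.
    """
    lookup = dict(front)
    if p.atp_yield not in lookup:
        raise ParetoError(
            f"yield {p.atp_yield} is not represented on the front")
    return max(0.0, p.cost - lookup[p.atp_yield])


class ECDF:
    """Right-continuous empirical CDF of a cost sample."""

    def __init__(self, values):
        v = np.asarray(sorted(values), dtype=float)
        if v.size == 0:
            raise ParetoError("cost_cdf needs a non-empty sample")
        self.x = v
        self.y = np.arange(1, v.size + 1) / v.size

    def __call__(self, t) -> float | np.ndarray:
        return np.searchsorted(self.x, t, side="right") / self.x.size


def cost_cdf(costs) -> ECDF:
    """Empirical CDF of minimal protein costs (CDF(max) = 1)."""
    return ECDF(costs)
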
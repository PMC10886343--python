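"""Derringer desirability functions and multi-response optimization.

Each fitted response is mapped to a desirability d in [0, 1] through a
(optionally powered) linear ramp between a lower and an upper anchor; the
joint objective is the weighted geometric mean

    D = (d1^w1 * d2^w2 * ... * dn^wn)^(1 / sum(w))

maximized over the coded design cube [-1, 1]^3.  The search is a dense grid
scan followed by Nelder-Mead refinement from the best grid cell, so the
refined optimum can never be worse than the grid optimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .design import decode_point
from .rsm import quadratic_model_matrix


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal for one response: direction, anchors, weight, ramp exponent."""

    response: str
    kind: str = "maximize"  # maximize | minimize | target
    low: float = 0.0
    high: float = 1.0
    target: float | None = None
    weight: float = 1.0
    shape: float = 1.0  # ramp exponent s; 1 = linear

    def __post_init__(self):
        if self.kind not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError("require low < high")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.kind == "target" and self.target is None:
            raise ValueError("target goal needs a target value")


def desirability_value(y, goal: DesirabilityGoal):
    """Desirability of response value(s) ``y`` under ``goal``; clamped to [0, 1]."""
    y = np.asarray(y, dtype=float)
    L, U, s = goal.low, goal.high, goal.shape
    if goal.kind == "maximize":
        d = np.clip((y - L) / (U - L), 0.0, 1.0) ** s
    elif goal.kind == "minimize":
        d = np.clip((U - y) / (U - L), 0.0, 1.0) ** s
    else:  # target
        T = goal.target
        left = np.clip((y - L) / (T - L), 0.0, 1.0)
        right = np.clip((U - y) / (U - T), 0.0, 1.0)
        d = np.where(y <= T, left, right) ** s
    return d if d.ndim else float(d)


def overall_desirability(d_values, weights=None):
    """Weighted geometric mean of per-response desirabilities.

    Zero desirability in any component annihilates D (the geometric mean).
    """
    d = np.asarray(d_values, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d), axis=-1) / np.sum(w)))


@dataclass
class OptimizationResult:
    """Joint desirability optimum in coded and actual units."""

    coded: np.ndarray
    actual: np.ndarray
    predicted: dict  # response -> predicted value at the optimum
    desirabilities: dict  # response -> d_i
    overall: float
    grid_best: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "coded": [float(v) for v in self.coded],
                "actual": [float(v) for v in self.actual],
                "predicted": {k: float(v) for k, v in self.predicted.items()},
                "desirabilities": {k: float(v) for k, v in self.desirabilities.items()},
                "overall_desirability": self.overall,
            },
            indent=2,
        )


def goals_from_observed(responses: dict, weight: float = 1.0) -> list[DesirabilityGoal]:
    """Maximize goals with ramps anchored at each response's observed range.

    This is the conventional default when the analyst states no explicit
    limits: d = 0 at the observed minimum, d = 1 at the observed maximum.
    """
    goals = []
    for name, y in responses.items():
        y = np.asarray(y, dtype=float)
        goals.append(
            DesirabilityGoal(
                response=name, kind="maximize",
                low=float(y.min()), high=float(y.max()), weight=weight,
            )
        )
    return goals


def optimize_desirability(
    models,
    goals,
    factors,
    grid_step: float = 0.01,
    grid_dump: bool = False,
) -> OptimizationResult:
    """Maximize overall desirability of several fitted surfaces over [-1,1]^3.

    Parameters
    ----------
    models : mapping of response name -> fitted QuadraticSurface
    goals : list of DesirabilityGoal covering every model
    factors : the three FactorSpec used to decode the optimum
    grid_step : coded grid resolution of the initial dense scan
    grid_dump : when True, attach the scanned grid (coded points and D) as
        ``result.grid_`` for contour export.
    """
    goal_map = {g.response: g for g in goals}
    missing = [name for name in models if name not in goal_map]
    if missing:
        raise ValueError(f"no desirability goal for response(s): {missing}")
    names = list(models)
    weights = np.array([goal_map[n].weight for n in names])

    def d_components(points):
        M = quadratic_model_matrix(points)
        return np.column_stack(
            [
                desirability_value(M @ models[n].coef_, goal_map[n])
                for n in names
            ]
        )

    def overall(points):
        d = d_components(points)
        wsum = weights.sum()
        return np.prod(d ** (weights / wsum), axis=1)

    # dense grid scan
    g = np.arange(-1.0, 1.0 + grid_step / 2, grid_step)
    G = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    D_grid = overall(G)
    i_best = int(np.argmax(D_grid))
    grid_best = float(D_grid[i_best])
    if grid_best == 0.0:
        warnings.warn(
            "desirability surface is zero everywhere on the grid; "
            "returning the grid point closest to the center",
            stacklevel=2,
        )
        norms = np.linalg.norm(G, axis=1)
        i_best = int(np.argmin(norms))
    # tie-break toward the smallest coded norm
    ties = np.flatnonzero(D_grid == D_grid[i_best])
    if len(ties) > 1:
        i_best = int(ties[np.argmin(np.linalg.norm(G[ties], axis=1))])

    # simplex refinement from the best grid cell, then a bounded
    # quasi-Newton polish (the surface can be nearly flat along a factor)
    neg = lambda x: -overall(np.clip(x, -1, 1)[None, :])[0]
    res = optimize.minimize(
        neg, G[i_best], method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
    )
    x_ref = np.clip(res.x, -1, 1)
    res2 = optimize.minimize(neg, x_ref, method="L-BFGS-B", bounds=[(-1, 1)] * 3)
    candidates = [G[i_best], x_ref, np.clip(res2.x, -1, 1)]
    D_cand = [overall(np.asarray(c)[None, :])[0] for c in candidates]
    x_opt = np.asarray(candidates[int(np.argmax(D_cand))], dtype=float)
    D_opt = float(max(D_cand))

    M_opt = quadratic_model_matrix(x_opt)
    predicted = {n: float((M_opt @ models[n].coef_)[0]) for n in names}
    desir = {
        n: float(desirability_value(predicted[n], goal_map[n])) for n in names
    }
    result = OptimizationResult(
        coded=x_opt,
        actual=decode_point(x_opt, factors),
        predicted=predicted,
        desirabilities=desir,
        overall=D_opt,
        grid_best=grid_best,
    )
    if grid_dump:
        result.grid_ = (G, D_grid)
    return result
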
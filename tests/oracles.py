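"""Independent brute-force oracles used to cross-check the solvers.

These deliberately share no code path with the package: the LP oracle
enumerates basic feasible points of the flux polytope directly, the cone
oracle enumerates support-minimal nonnegative null-space vectors with
sympy's exact linear algebra, and the parsimonious-flux oracle is a
separate absolute-value LP on the *unsplit* model.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, product

import numpy as np
import sympy
from scipy.optimize import linprog


def brute_force_min_cost(aug, fraction: float, optimum: float) -> float:
    """Minimal cost-sink flux at the fixed objective value, by vertex
    enumeration of {S·v = 0, v_obj = f·opt, bounds}."""
    model = aug.base
    S = model.S.toarray()
    ridx = model.reaction_index()
    n = S.shape[1]
    obj_row = np.zeros((1, n))
    obj_row[0, ridx[model.objective_id]] = 1.0
    A = np.vstack([S, obj_row])
    b = np.concatenate([np.zeros(S.shape[0]), [fraction * optimum]])
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    r = np.linalg.matrix_rank(A)
    k = n - r
    j_sink = ridx[aug.cost_sink_id]
    best = math.inf
    tol = 1e-7
    for fixed in combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        choices = []
        for j in fixed:
            opts = [v for v in (lb[j], ub[j]) if math.isfinite(v)]
            if not opts:
                break
            choices.append(sorted(set(opts)))
        else:
            A_free = A[:, free]
            if np.linalg.matrix_rank(A_free) < len(free):
                continue
            for vals in product(*choices):
                rhs = b - A[:, fixed] @ np.array(vals)
                x_free, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                v = np.empty(n)
                v[list(fixed)] = vals
                v[free] = x_free
                if np.max(np.abs(A @ v - b)) > tol:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                best = min(best, v[j_sink])
    return best


def support_minimal_rays(
    rows: list[dict[int, Fraction]], n_cols: int
) -> set[tuple[Fraction, ...]]:
    """All support-minimal nonnegative null-space rays of {v≥0: A·v=0},
    by exhaustive support enumeration with exact arithmetic."""
    A = sympy.zeros(len(rows), n_cols)
    for i, row in enumerate(rows):
        for j, coef in row.items():
            A[i, j] = sympy.Rational(coef.numerator, coef.denominator)
    minimal: list[frozenset[int]] = []
    rays: set[tuple[Fraction, ...]] = set()
    for size in range(1, n_cols + 1):
        for support in combinations(range(n_cols), size):
            sup = frozenset(support)
            if any(m < sup for m in minimal):
                continue
            sub = A[:, list(support)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            vec = null[0]
            entries = [vec[i] for i in range(len(support))]
            if all(e > 0 for e in entries):
                pass
            elif all(e < 0 for e in entries):
                entries = [-e for e in entries]
            else:
                continue
            denoms = [sympy.fraction(e)[1] for e in entries]
            lcm = sympy.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
            ints = [sympy.Integer(e * lcm) for e in entries]
            g = sympy.igcd(*ints) if len(ints) > 1 else ints[0]
            ray = [Fraction(0)] * n_cols
            for j, e in zip(support, ints):
                ray[j] = Fraction(int(e // g))
            minimal.append(sup)
            rays.add(tuple(ray))
    return rays


def min_total_enzyme_flux(model, enzyme_ids, target: float) -> float:
    """Parsimonious baseline: minimize Σ|v| over enzyme reactions at a
    fixed objective flux, on the original (unsplit) model."""
    S = model.S.toarray()
    ridx = model.reaction_index()
    n = S.shape[1]
    k = len(enzyme_ids)
    # variables: v (n), t (k) with t >= |v_enzyme|
    A_eq = np.zeros((S.shape[0] + 1, n + k))
    A_eq[: S.shape[0], :n] = S
    A_eq[S.shape[0], ridx[model.objective_id]] = 1.0
    b_eq = np.concatenate([np.zeros(S.shape[0]), [target]])
    A_ub = np.zeros((2 * k, n + k))
    for i, rid in enumerate(enzyme_ids):
        j = ridx[rid]
        A_ub[2 * i, j] = 1.0
        A_ub[2 * i, n + i] = -1.0
        A_ub[2 * i + 1, j] = -1.0
        A_ub[2 * i + 1, n + i] = -1.0
    b_ub = np.zeros(2 * k)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions] + [
        (0, None)
    ] * k
    c = np.concatenate([np.zeros(n), np.ones(k)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    assert res.success, res.message
    return float(res.fun)


def in_cone(rays: list[tuple[Fraction, ...]], v: np.ndarray, tol=1e-7) -> bool:
    """Is v a nonnegative combination of the given rays? (LP feasibility)"""
    if not rays:
        return bool(np.max(np.abs(v)) < tol)
    R = np.array([[float(x) for x in ray] for ray in rays]).T
    res = linprog(
        np.zeros(R.shape[1]), A_eq=R, b_eq=v,
        bounds=[(0, None)] * R.shape[1], method="highs",
    )
    return bool(res.success)
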
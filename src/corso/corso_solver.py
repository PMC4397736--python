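"""Two-step protein-cost-minimal flux balance (the corsoFBA solve).

Step one maximizes the objective (biomass) flux by ordinary FBA on the
cost-augmented model.  Step two fixes the objective at a chosen fraction f
of that optimum by an equality constraint and minimizes the flux through
the cost sink — i.e. the total protein cost — returning the cheapest flux
distribution that achieves the prescribed sub-optimal objective value.
Sweeping f from 0.5 to 1.0 traces how pathway usage changes across the
near-optimal solution space.

LPs are solved with scipy's HiGHS backend.  Alternate cost-minimal optima
are disambiguated by a secondary lexicographic minimization of the summed
split-direction fluxes, which makes solver output reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .cost_model import CostAugmentedModel
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

#: |v| below this is snapped to exactly 0 after a solve.
FLUX_ZERO_TOL = 1e-9
#: slack allowed when pinning the cost in the lexicographic clean-up LP
_LEX_SLACK = 1e-9


class SolverError(RuntimeError):
    pass


@dataclass
class MediumSpec:
    """Growth-medium bounds applied to exchange reactions.

    ``uptake_bounds`` maps an exchange id to the maximum uptake magnitude
    (the exchange lower bound becomes −value); exchanges listed in
    ``blocked_secretions`` get a release bound of 0.
    """

    uptake_bounds: dict[str, float] = field(default_factory=dict)
    blocked_secretions: list[str] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MediumSpec":
        """Read ``medium.tsv`` (columns: exchange_id, uptake_bound,
        secretion_allowed)."""
        df = pd.read_csv(path, sep="\t")
        expected = ("exchange_id", "uptake_bound", "secretion_allowed")
        if tuple(df.columns) != expected:
            raise ValueError(f"medium file header must be {expected}")
        uptake = {}
        blocked = []
        for row in df.itertuples(index=False):
            uptake[str(row.exchange_id)] = float(row.uptake_bound)
            if not int(row.secretion_allowed):
                blocked.append(str(row.exchange_id))
        return cls(uptake_bounds=uptake, blocked_secretions=blocked)


def apply_medium(model: MetabolicModel, medium: MediumSpec | None) -> MetabolicModel:
    """Return a copy of ``model`` with medium bounds applied.

    Exchange reactions follow the ``met → ∅`` convention, so uptake is
    negative flux: an uptake bound u sets the exchange lower bound to −u.
    """
    out = model.copy()
    if medium is None:
        return out
    ridx = {r.id: r for r in out.reactions}
    for ex_id, bound in medium.uptake_bounds.items():
        if ex_id not in ridx:
            raise KeyError(f"medium references unknown exchange {ex_id!r}")
        if not math.isfinite(bound):
            raise ValueError(f"uptake bound for {ex_id!r} must be finite")
        ridx[ex_id].lower_bound = -abs(bound)
    for ex_id in medium.blocked_secretions:
        if ex_id not in ridx:
            raise KeyError(f"medium references unknown exchange {ex_id!r}")
        ridx[ex_id].upper_bound = 0.0
    return out


@dataclass
class CorsoSolution:
    """One sub-optimal solve: the cheapest flux vector at objective
    fraction f."""

    fraction: float
    objective_value: float
    net_fluxes: dict[str, float]
    split_fluxes: dict[str, float]
    total_cost: float
    status: str  # "optimal" | "infeasible"
    aug: CostAugmentedModel | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------


def _lp_arrays(model: MetabolicModel):
    S = model.S
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds, model.reaction_index()


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    return res


def maximize_objective(
    aug: CostAugmentedModel, medium: MediumSpec | None = None
) -> tuple[float, dict[str, float]]:
    """FBA step: maximize the objective flux on the augmented model."""
    model = apply_medium(aug.base, medium)
    S, bounds, ridx = _lp_arrays(model)
    n = len(model.reactions)
    c = np.zeros(n)
    c[ridx[model.objective_id]] = -1.0
    res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    if res.status == 3:
        raise SolverError("objective maximization is unbounded")
    if not res.success:
        raise SolverError(f"objective maximization failed: {res.message}")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return float(-res.fun), fluxes


def solve_corso(
    aug: CostAugmentedModel,
    medium: MediumSpec | None = None,
    fraction: float = 1.0,
    optimum: float | None = None,
    objective_mode: str = "equality",
) -> CorsoSolution:
    """Minimize total protein cost at a fixed objective fraction.

    The objective flux is pinned to ``fraction × optimum`` by an equality
    constraint (``objective_mode="at_least"`` relaxes it to a lower bound).
    Among cost-minimal distributions, the one with minimal summed
    split-direction flux is returned (deterministic tie-break), so returned
    solutions never run a split pair in both directions at once.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if objective_mode not in ("equality", "at_least"):
        raise ValueError(f"unknown objective_mode {objective_mode!r}")
    if optimum is None:
        optimum, _ = maximize_objective(aug, medium)
    model = apply_medium(aug.base, medium)
    S, bounds, ridx = _lp_arrays(model)
    n = len(model.reactions)
    m = S.shape[0]
    j_obj = ridx[model.objective_id]
    j_sink = ridx[aug.cost_sink_id]
    target = fraction * optimum

    obj_row = np.zeros((1, n))
    obj_row[0, j_obj] = 1.0
    if objective_mode == "equality":
        A_eq = np.vstack([S.toarray(), obj_row])
        b_eq = np.concatenate([np.zeros(m), [target]])
        A_ub, b_ub = None, None
    else:
        A_eq, b_eq = S.toarray(), np.zeros(m)
        A_ub, b_ub = -obj_row, np.array([-target])

    c = np.zeros(n)
    c[j_sink] = 1.0
    res = _solve_lp(c, A_eq, b_eq, bounds, A_ub, b_ub)
    if not res.success:
        logger.warning(
            "solve_corso infeasible at fraction %.4g (%s)", fraction, res.message
        )
        return CorsoSolution(fraction, target, {}, {}, math.nan, "infeasible", aug)
    total_cost = float(res.fun)

    # lexicographic clean-up: pin the cost, minimize summed split fluxes
    split_vars = [
        fid for fid, bid in aug.split_map.values() if bid is not None
    ] + [bid for _, bid in aug.split_map.values() if bid is not None]
    x = res.x
    if split_vars:
        cost_row = np.zeros((1, n))
        cost_row[0, j_sink] = 1.0
        A_ub2 = cost_row if A_ub is None else np.vstack([A_ub, cost_row])
        b_ub2 = np.array([total_cost * (1 + _LEX_SLACK) + _LEX_SLACK])
        if b_ub is not None:
            b_ub2 = np.concatenate([b_ub, b_ub2])
        c2 = np.zeros(n)
        for rid in split_vars:
            c2[ridx[rid]] = 1.0
        res2 = _solve_lp(c2, A_eq, b_eq, bounds, A_ub2, b_ub2)
        if res2.success:
            x = res2.x

    split_fluxes = {
        r.id: (0.0 if abs(v) < FLUX_ZERO_TOL else float(v))
        for r, v in zip(model.reactions, x)
    }
    net = aug.net_fluxes(split_fluxes)
    net = {k: (0.0 if abs(v) < FLUX_ZERO_TOL else v) for k, v in net.items()}
    return CorsoSolution(
        fraction=fraction,
        objective_value=target,
        net_fluxes=net,
        split_fluxes=split_fluxes,
        total_cost=aug.total_cost(split_fluxes),
        status="optimal",
        aug=aug,
    )


def sweep(
    aug: CostAugmentedModel,
    medium: MediumSpec | None = None,
    fractions: Sequence[float] | None = None,
) -> list[CorsoSolution]:
    """Cost-minimal solves over a grid of objective fractions.

    Default grid: 0.50 to 1.00 in steps of 0.01.  Per-fraction failures are
    reported and skipped; the sweep continues.
    """
    if fractions is None:
        fractions = default_fraction_grid()
    fractions = sorted(fractions)
    optimum, _ = maximize_objective(aug, medium)
    out: list[CorsoSolution] = []
    failures: list[float] = []
    for f in fractions:
        try:
            sol = solve_corso(aug, medium, fraction=f, optimum=optimum)
        except SolverError as exc:
            logger.warning("sweep: fraction %.4g failed (%s)", f, exc)
            failures.append(f)
            continue
        if not sol.ok:
            failures.append(f)
            continue
        out.append(sol)
    if failures:
        logger.warning("sweep: %d of %d fractions infeasible: %s",
                       len(failures), len(fractions), failures)
    return out


def default_fraction_grid(start: float = 0.50, stop: float = 1.00,
                          step: float = 0.01) -> list[float]:
    n = int(round((stop - start) / step))
    return [round(start + i * step, 10) for i in range(n + 1)]


def normalize_fluxes(
    sol: CorsoSolution,
    mode: str = "glc_g6p",
    glc_g6p_id: str | None = None,
) -> dict[str, float]:
    """Normalize a solution's net fluxes for cross-condition comparison.

    ``"glc_g6p"`` divides by the flux of the glucose → glucose-6-phosphate
    reaction (``glc_g6p_id``); ``"total_enzyme_flux"`` divides by the summed
    absolute net flux through enzyme-associated reactions.
    """
    if not sol.ok:
        raise ValueError("cannot normalize an infeasible solution")
    if mode == "glc_g6p":
        if glc_g6p_id is None:
            raise ValueError("glc_g6p mode requires glc_g6p_id")
        denom = sol.net_fluxes.get(glc_g6p_id)
        if denom is None:
            raise KeyError(f"reaction {glc_g6p_id!r} not in solution")
    elif mode == "total_enzyme_flux":
        if sol.aug is None or sol.aug.coefficients is None:
            raise ValueError("solution lacks cost coefficients for enzyme flags")
        coeffs = sol.aug.coefficients
        denom = sum(
            abs(v)
            for rid, v in sol.net_fluxes.items()
            if coeffs.per_reaction[rid].forward > 0
            or (coeffs.per_reaction[rid].backward or 0.0) > 0
        )
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if abs(denom) < FLUX_ZERO_TOL:
        raise ZeroDivisionError(f"normalization denominator is zero (mode={mode})")
    return {rid: v / denom for rid, v in sol.net_fluxes.items()}
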
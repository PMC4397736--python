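"""Fundamental pathway analysis: currency-reduced extreme pathways.

Extreme-pathway decompositions of genome-scale networks explode
combinatorially, largely because ubiquitous cofactors (ATP/ADP, NAD(H),
protons, water, phosphate, ...) must each be balanced, and the many small
loops that can balance them multiply pathways that share one metabolic
backbone.  The analysis here removes a chosen set of such currency
metabolites from every reaction and compartment, enumerates the extreme
rays of the reduced flux cone exactly (rational arithmetic, reversible
reactions split into irreversible halves), and annotates each resulting
*fundamental pathway* with:

* its imbalance — the net production S_original·v it would cause in the
  unreduced model (e.g. +2 ATP per glucose for glycolysis to lactate);
* its ATP production potential, crediting imbalances of other energy
  carriers (NADH, ubiquinol-8, ...) at the cheapest rate the full model
  can convert them to ATP;
* its protein cost per mmol of ATP;
* an optimal / near-optimal (OP/NOP) classification on the
  (ATP per glucose, cost per ATP) plane.

Internal cycles with no exchange flux (type III pathways) are detected and
flagged rather than scored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import reduce
from math import gcd
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cost_model import (
    BACKWARD_SUFFIX,
    CostAugmentedModel,
    CostCoefficients,
    FORWARD_SUFFIX,
)
from .corso_solver import MediumSpec, _lp_arrays, _solve_lp, apply_medium
from .model_io import MetabolicModel, Reaction

logger = logging.getLogger(__name__)

#: Currency metabolites removed by default, matched across compartments by
#: base name.  Users override this per model; the classic loop-formers are
#: the phosphate/redox/proton/water carriers.
DEFAULT_CURRENCY = (
    "atp", "adp", "amp", "pi", "ppi",
    "nad", "nadh", "nadp", "nadph",
    "h", "h2o", "coa", "co2",
)

#: Energy carriers credited toward ATP potential, with their oxidized
#: partners (base names).
DEFAULT_CARRIER_PAIRS = {
    "nadh": "nad",
    "nadph": "nadp",
    "q8h2": "q8",
    "fadh2": "fad",
}

#: Enumeration refuses networks with more split columns than this
#: (extreme-ray counts grow exponentially).
MAX_COLUMNS_DEFAULT = 80


def metabolite_base_name(met_id: str, compartment: str) -> str:
    """Strip the compartment tag from a metabolite id.

    Handles both ``glc__D_c`` (BiGG underscore style) and ``glc__D[c]``.
    """
    for suffix in (f"_{compartment}", f"[{compartment}]"):
        if met_id.endswith(suffix):
            return met_id[: -len(suffix)]
    return met_id


def _frac(x: float | int | Fraction) -> Fraction:
    """Exact rational for a stoichiometric coefficient.

    Decimal-looking floats are recovered to small denominators; exotic
    floats fall back to their exact binary value.
    """
    if isinstance(x, Fraction):
        return x
    f = Fraction(x)
    approx = f.limit_denominator(10**6)
    return approx if abs(approx - f) < Fraction(1, 10**12) else f


# ---------------------------------------------------------------------------
# currency removal
# ---------------------------------------------------------------------------


@dataclass
class ReductionWarning:
    kind: str  # "absent_currency" | "sink_or_source"
    subject: str
    detail: str


@dataclass
class ReducedModel:
    """A model with currency metabolites deleted from every reaction."""

    base: MetabolicModel
    removed_metabolites: list[str]
    removed_reactions: list[str]
    warnings: list[ReductionWarning] = field(default_factory=list)


def reduce_model(
    model: MetabolicModel, currency_ids: Sequence[str] = DEFAULT_CURRENCY
) -> ReducedModel:
    """Delete currency metabolites (all compartments) from a model.

    Reactions emptied by the removal are dropped; a retained reaction whose
    surviving stoichiometry is one-signed (it became a pure source or sink)
    is kept but recorded as a warning, since it would act as an implicit
    exchange during enumeration.  An id in ``currency_ids`` matching no
    metabolite is a warned no-op.
    """
    wanted = {c.lower() for c in currency_ids}
    warnings: list[ReductionWarning] = []
    removed_mets = [
        m.id
        for m in model.metabolites
        if metabolite_base_name(m.id, m.compartment).lower() in wanted
    ]
    found_bases = {
        metabolite_base_name(m.id, m.compartment).lower()
        for m in model.metabolites
        if m.id in set(removed_mets)
    }
    for name in sorted(wanted - found_bases):
        warnings.append(
            ReductionWarning("absent_currency", name,
                             f"currency metabolite {name!r} not in model")
        )
    removed_set = set(removed_mets)
    new_reactions: list[Reaction] = []
    removed_rxns: list[str] = []
    for rxn in model.reactions:
        stoich = {m: c for m, c in rxn.stoichiometry.items() if m not in removed_set}
        if not stoich:
            removed_rxns.append(rxn.id)
            continue
        if len(stoich) < len(rxn.stoichiometry) and not rxn.is_exchange:
            signs = {c > 0 for c in stoich.values()}
            if len(signs) == 1:
                kind = "source" if signs == {True} else "sink"
                warnings.append(
                    ReductionWarning(
                        "sink_or_source", rxn.id,
                        f"reaction {rxn.id!r} became a pure {kind} after removal",
                    )
                )
        new_reactions.append(
            Reaction(rxn.id, stoich, rxn.lower_bound, rxn.upper_bound,
                     enzyme_associated=rxn.enzyme_associated, name=rxn.name)
        )
    retained_ids = {r.id for r in new_reactions}
    objective = (
        model.objective_id
        if model.objective_id in retained_ids
        else new_reactions[0].id
    )
    reduced = MetabolicModel(
        metabolites=[m for m in model.metabolites if m.id not in removed_set],
        reactions=new_reactions,
        objective_id=objective,
        id=model.id + "_reduced",
    )
    return ReducedModel(reduced, removed_mets, removed_rxns, warnings)


# ---------------------------------------------------------------------------
# split-column representation and exact extreme-ray enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitColumn:
    """One irreversible column of the split network."""

    id: str
    reaction_id: str
    direction: str  # "forward" | "backward"
    stoichiometry: Mapping[str, Fraction]
    is_exchange: bool


def split_columns(model: MetabolicModel) -> list[SplitColumn]:
    """Irreversible column set: reversible reactions contribute a forward
    and a negated backward column; one-directional reactions one column.

    Exchange reactions are included the same way, so a reversible exchange
    yields separate uptake and secretion columns.
    """
    cols: list[SplitColumn] = []
    for rxn in model.reactions:
        stoich = {m: _frac(c) for m, c in rxn.stoichiometry.items()}
        fwd_ok = rxn.upper_bound > 0
        bwd_ok = rxn.lower_bound < 0
        if fwd_ok and bwd_ok:
            cols.append(SplitColumn(rxn.id + FORWARD_SUFFIX, rxn.id, "forward",
                                    stoich, rxn.is_exchange))
            cols.append(SplitColumn(rxn.id + BACKWARD_SUFFIX, rxn.id, "backward",
                                    {m: -c for m, c in stoich.items()},
                                    rxn.is_exchange))
        elif fwd_ok:
            cols.append(SplitColumn(rxn.id, rxn.id, "forward", stoich,
                                    rxn.is_exchange))
        elif bwd_ok:
            cols.append(SplitColumn(rxn.id + BACKWARD_SUFFIX, rxn.id, "backward",
                                    {m: -c for m, c in stoich.items()},
                                    rxn.is_exchange))
    return cols


def _canonical(ray: tuple[Fraction, ...]) -> tuple[Fraction, ...]:
    """Scale a ray to the smallest nonnegative integer representation."""
    denoms = [v.denominator for v in ray if v]
    if not denoms:
        return ray
    lcm = reduce(lambda a, b: a * b // gcd(a, b), denoms, 1)
    ints = [int(v * lcm) for v in ray]
    g = reduce(gcd, (abs(i) for i in ints if i), 0)
    return tuple(Fraction(i // g) for i in ints) if g else ray


def extreme_rays(
    rows: Sequence[Mapping[int, Fraction]], n_cols: int
) -> list[tuple[Fraction, ...]]:
    """Extreme rays of {v ≥ 0 : A·v = 0}, by double description.

    ``rows`` are the equality constraints as sparse {column index:
    coefficient} maps.  Constraints are inserted in order of increasing
    support (the classic heuristic); after every insertion the candidate
    set is pruned to proportional-unique, support-minimal rays — for cones
    of this form the support-minimal nonzero solutions are exactly the
    extreme rays.  All arithmetic is exact.
    """
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(int(i == j)) for j in range(n_cols)) for i in range(n_cols)
    ]
    zero = Fraction(0)
    for row in sorted(rows, key=lambda r: (len(r), sorted(r.items()))):
        if not row:
            continue
        vals = [sum(coef * ray[j] for j, coef in row.items()) for ray in rays]
        keep = [ray for ray, d in zip(rays, vals) if d == 0]
        pos = [(ray, d) for ray, d in zip(rays, vals) if d > 0]
        neg = [(ray, d) for ray, d in zip(rays, vals) if d < 0]
        combos = [
            tuple(dp * rn[j] - dn * rp[j] for j in range(n_cols))
            for rp, dp in pos
            for rn, dn in neg
        ]
        rays = _prune(keep + [_canonical(c) for c in combos])
    return rays


def _prune(rays: list[tuple[Fraction, ...]]) -> list[tuple[Fraction, ...]]:
    uniq = list({_canonical(r): None for r in rays if any(r)})
    supports = [frozenset(j for j, v in enumerate(r) if v) for r in uniq]
    out = []
    for i, (ray, sup) in enumerate(zip(uniq, supports)):
        minimal = not any(
            other < sup for k, other in enumerate(supports) if k != i
        )
        if minimal:
            out.append(ray)
    return out


@dataclass
class FundamentalPathway:
    """An extreme ray of the currency-reduced cone, with annotations."""

    id: str
    flux: dict[str, Fraction]  # split-column id -> integer-scaled flux
    columns: dict[str, tuple[str, str]]  # column id -> (reaction id, direction)
    is_internal_loop: bool
    net_flux: dict[str, Fraction] = field(default_factory=dict)
    imbalance: dict[str, Fraction] = field(default_factory=dict)
    atp_potential: float | None = None
    total_cost: float | None = None
    cost_per_atp: float | None = None
    classification: str = "other"

    def scaled_net_flux(self, reference_id: str) -> dict[str, Fraction]:
        """Net flux scaled so |flux through reference_id| = 1."""
        ref = abs(self.net_flux.get(reference_id, Fraction(0)))
        if ref == 0:
            raise ZeroDivisionError(
                f"pathway {self.id} carries no flux through {reference_id!r}"
            )
        return {k: v / ref for k, v in self.net_flux.items()}


def enumerate_pathways(
    reduced: ReducedModel, max_columns: int = MAX_COLUMNS_DEFAULT
) -> list[FundamentalPathway]:
    """All fundamental pathways of a reduced model.

    The reduced network is split into irreversible columns, the extreme
    rays of {v ≥ 0 : S_reduced·v = 0} are enumerated exactly, trivial
    forward∘backward two-cycles are discarded, and each surviving ray is
    scaled to smallest integers.  Rays without any exchange flux are
    flagged as internal (type III) loops.
    """
    cols = split_columns(reduced.base)
    if len(cols) > max_columns:
        raise ValueError(
            f"network has {len(cols)} split columns; enumeration is exponential "
            f"and refused above {max_columns} (raise max_columns to override)"
        )
    midx = {m.id: i for i, m in enumerate(reduced.base.metabolites)}
    rows: list[dict[int, Fraction]] = [dict() for _ in midx]
    for j, col in enumerate(cols):
        for met, coef in col.stoichiometry.items():
            rows[midx[met]][j] = coef
    rays = extreme_rays(rows, len(cols))

    pathways: list[FundamentalPathway] = []
    counter = 0
    for ray in sorted(rays):
        support = {cols[j].id for j, v in enumerate(ray) if v}
        # trivial two-cycle: forward and backward of one reversible reaction
        rxns = {cols[j].reaction_id for j, v in enumerate(ray) if v}
        if len(rxns) == 1 and len(support) == 2:
            continue
        flux = {cols[j].id: v for j, v in enumerate(ray) if v}
        columns = {cols[j].id: (cols[j].reaction_id, cols[j].direction)
                   for j, v in enumerate(ray) if v}
        is_loop = all(
            not cols[j].is_exchange for j, v in enumerate(ray) if v
        ) if flux else True
        net: dict[str, Fraction] = {}
        for j, v in enumerate(ray):
            if not v:
                continue
            sign = 1 if cols[j].direction == "forward" else -1
            net[cols[j].reaction_id] = net.get(cols[j].reaction_id, Fraction(0)) + sign * v
        counter += 1
        pathways.append(
            FundamentalPathway(
                id=f"FP{counter}",
                flux=flux,
                columns=columns,
                is_internal_loop=is_loop,
                net_flux={k: v for k, v in net.items() if v},
            )
        )
    return pathways


# ---------------------------------------------------------------------------
# imbalance and ATP-potential annotation
# ---------------------------------------------------------------------------


def full_model_imbalance(
    model: MetabolicModel, net_flux: Mapping[str, Fraction]
) -> dict[str, Fraction]:
    """S_original · v, exactly; nonzero entries only."""
    ridx = {r.id: r for r in model.reactions}
    acc: dict[str, Fraction] = {}
    for rxn_id, v in net_flux.items():
        if rxn_id not in ridx:
            raise KeyError(f"flux references unknown reaction {rxn_id!r}")
        for met, coef in ridx[rxn_id].stoichiometry.items():
            acc[met] = acc.get(met, Fraction(0)) + _frac(coef) * v
    return {m: v for m, v in acc.items() if v}


def annotate_imbalance(
    pathway: FundamentalPathway, full: MetabolicModel
) -> FundamentalPathway:
    """Attach the pathway's full-model imbalance (net currency production).

    Exchange reactions are part of the pathway, so metabolites balanced in
    the reduced model stay balanced here; only removed metabolites can be
    imbalanced.
    """
    pathway.imbalance = full_model_imbalance(full, pathway.net_flux)
    return pathway


def carrier_conversion(
    aug: CostAugmentedModel,
    carrier_id: str,
    medium: MediumSpec | None = None,
    atp_drain_id: str = "ATPM",
    carrier_pairs: Mapping[str, str] = DEFAULT_CARRIER_PAIRS,
) -> tuple[float, float]:
    """Cheapest ATP yield of one unit of a reduced energy carrier.

    With every exchange uptake closed, a pseudo-reaction regenerating the
    reduced carrier from its oxidized partner (e.g. NAD⁺ → NADH) is fixed
    at flux 1, the ATP drain (hydrolysis/maintenance reaction
    ``atp_drain_id``) is maximized, and at that yield the protein cost is
    minimized.  Returns ``(atp_yield, conversion_cost)`` per unit carrier;
    a carrier that cannot drive ATP production returns ``(0, 0)`` with a
    warning.  ATP itself converts identically: ``(1, 0)``.
    """
    full = aug.original
    met = next((m for m in full.metabolites if m.id == carrier_id), None)
    if met is None:
        raise KeyError(f"carrier metabolite {carrier_id!r} not in model")
    base = metabolite_base_name(met.id, met.compartment).lower()
    if base == "atp":
        return 1.0, 0.0
    ox_base = carrier_pairs.get(base)
    if ox_base is None:
        logger.warning("no oxidized partner known for carrier %r", carrier_id)
        return 0.0, 0.0
    ox_id = None
    for m in aug.base.metabolites:
        if (m.compartment == met.compartment
                and metabolite_base_name(m.id, m.compartment).lower() == ox_base):
            ox_id = m.id
            break
    if ox_id is None:
        logger.warning("oxidized partner %r of %r absent; conversion impossible",
                       ox_base, carrier_id)
        return 0.0, 0.0

    model = apply_medium(aug.base, medium)
    for rxn in model.reactions:
        if rxn.is_exchange and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    src = Reaction(
        f"CARRIER_SRC__{base}", {ox_id: -1.0, carrier_id: 1.0}, 1.0, 1.0,
        enzyme_associated=False, name=f"{base} regeneration source",
    )
    model = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=[r.copy() for r in model.reactions] + [src],
        objective_id=model.objective_id,
        id=model.id + f"_{base}_conv",
    )
    if atp_drain_id not in aug.split_map:
        raise KeyError(f"ATP drain reaction {atp_drain_id!r} not in model")
    drain_col = aug.split_map[atp_drain_id][0]
    S, bounds, ridx = _lp_arrays(model)
    n = len(model.reactions)
    c = np.zeros(n)
    c[ridx[drain_col]] = -1.0
    res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    if not res.success or -res.fun < 1e-9:
        logger.warning("carrier %r cannot drive ATP production", carrier_id)
        return 0.0, 0.0
    atp_yield = float(-res.fun)

    pin = np.zeros((1, n))
    pin[0, ridx[drain_col]] = 1.0
    A_eq = np.vstack([S.toarray(), pin])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [atp_yield]])
    c2 = np.zeros(n)
    c2[ridx[aug.cost_sink_id]] = 1.0
    res2 = _solve_lp(c2, A_eq, b_eq, bounds)
    if not res2.success:
        logger.warning("cost minimization failed for carrier %r", carrier_id)
        return atp_yield, 0.0
    return atp_yield, float(res2.fun)


def pathway_enzyme_cost(
    pathway: FundamentalPathway, coeffs: CostCoefficients
) -> float:
    """Protein cost of running the pathway at its recorded flux."""
    total = 0.0
    for col_id, v in pathway.flux.items():
        rxn_id, direction = pathway.columns[col_id]
        dc = coeffs.per_reaction[rxn_id]
        coef = dc.forward if direction == "forward" else (dc.backward or 0.0)
        total += float(v) * coef
    return total


def atp_potential(
    pathway: FundamentalPathway,
    conversions: Mapping[str, tuple[float, float]],
    carriers: Sequence[str],
    coeffs: CostCoefficients,
    full: MetabolicModel,
    glucose_exchange_id: str | None = None,
    atp_base: str = "atp",
) -> FundamentalPathway:
    """Score a pathway's ATP production potential and cost per ATP.

    The pathway is normalized per mmol glucose (unit flux through
    ``glucose_exchange_id``) when it takes up glucose, else per pathway
    unit.  ATP potential is the direct ATP imbalance plus each energy
    carrier's imbalance converted at its ATP yield; surplus carrier
    production adds, net consumption subtracts symmetrically.  Total cost
    is the pathway's own protein cost plus the cheapest conversion cost of
    its surplus carriers; cost per ATP is their ratio (+∞ when the
    potential is not positive).
    """
    comp_of = {m.id: m.compartment for m in full.metabolites}

    scale = Fraction(1)
    if glucose_exchange_id is not None:
        glc = abs(pathway.net_flux.get(glucose_exchange_id, Fraction(0)))
        if glc:
            scale = 1 / glc

    def base_sum(base_name: str) -> float:
        return float(
            sum(
                (v * scale for m, v in pathway.imbalance.items()
                 if metabolite_base_name(m, comp_of[m]).lower() == base_name),
                Fraction(0),
            )
        )

    potential = base_sum(atp_base)
    cost = pathway_enzyme_cost(pathway, coeffs) * float(scale)
    for carrier in carriers:
        cbase = metabolite_base_name(
            carrier, comp_of.get(carrier, "")
        ).lower() if carrier in comp_of else carrier.lower()
        if carrier not in conversions and cbase not in conversions:
            raise KeyError(f"carrier {carrier!r} missing from conversions map")
        c_yield, c_cost = conversions.get(carrier, conversions.get(cbase, (0, 0)))
        imb = base_sum(cbase)
        potential += imb * c_yield  # surplus adds, deficit subtracts
        if imb > 0:
            cost += imb * c_cost
    pathway.atp_potential = potential
    pathway.total_cost = cost
    pathway.cost_per_atp = cost / potential if potential > 0 else math.inf
    return pathway


def pareto_classify(
    pathways: Iterable[FundamentalPathway], margin: float = 0.10
) -> list[FundamentalPathway]:
    """OP/NOP classification on the (ATP potential, cost per ATP) plane.

    Optimal pathways (OP) are the non-dominated frontier when maximizing
    ATP potential per glucose and minimizing cost per ATP.  A dominated
    pathway is near-optimal (NOP) unless some OP beats it by more than
    ``margin`` (relative) on *both* axes simultaneously.  Internal loops
    and pathways with non-positive ATP potential stay "other".
    """
    pathways = list(pathways)
    scored = [
        p for p in pathways
        if not p.is_internal_loop
        and p.atp_potential is not None
        and p.atp_potential > 0
        and p.cost_per_atp is not None
        and math.isfinite(p.cost_per_atp)
    ]
    for p in pathways:
        p.classification = "other"

    def dominates(a: FundamentalPathway, b: FundamentalPathway) -> bool:
        return (
            a.atp_potential >= b.atp_potential
            and a.cost_per_atp <= b.cost_per_atp
            and (a.atp_potential > b.atp_potential or a.cost_per_atp < b.cost_per_atp)
        )

    ops = [p for p in scored if not any(dominates(q, p) for q in scored if q is not p)]
    for p in ops:
        p.classification = "OP"
    for p in scored:
        if p.classification == "OP":
            continue
        far = any(
            q.atp_potential >= p.atp_potential * (1 + margin)
            and q.cost_per_atp <= p.cost_per_atp * (1 - margin)
            for q in ops
        )
        p.classification = "other" if far else "NOP"
    return pathways


# ---------------------------------------------------------------------------
# recovering full-model balance
# ---------------------------------------------------------------------------


def recover_balancing_fluxes(
    pathway: FundamentalPathway,
    full: MetabolicModel,
    reduced: ReducedModel,
) -> dict[str, Fraction]:
    """Fluxes through the removed balancing reactions that cancel a
    pathway's imbalance.

    Solves S_removed·x = −imbalance exactly (Gauss–Jordan over rationals,
    free variables at 0), so that pathway + x is balanced in the original
    model.  Raises if no exact balancing assignment exists; warns when a
    balancing flux runs against a removed reaction's declared bounds.
    """
    removed = [full.get_reaction(rid) for rid in reduced.removed_reactions]
    if not removed:
        raise ValueError("reduction removed no reactions; nothing to add back")
    mets = sorted(
        {m for r in removed for m in r.stoichiometry} | set(pathway.imbalance)
    )
    midx = {m: i for i, m in enumerate(mets)}
    A = [[Fraction(0)] * len(removed) for _ in mets]
    for j, rxn in enumerate(removed):
        for met, coef in rxn.stoichiometry.items():
            A[midx[met]][j] = _frac(coef)
    b = [-pathway.imbalance.get(m, Fraction(0)) for m in mets]
    x = _exact_solve(A, b)
    if x is None:
        raise ValueError(
            f"pathway {pathway.id}: imbalance cannot be cancelled by the "
            "removed reactions"
        )
    out: dict[str, Fraction] = {}
    for rxn, v in zip(removed, x):
        if v:
            if (v > 0 and rxn.upper_bound <= 0) or (v < 0 and rxn.lower_bound >= 0):
                logger.warning(
                    "balancing flux %s through %s violates its bounds", v, rxn.id
                )
            out[rxn.id] = v
    return out


def _exact_solve(
    A: list[list[Fraction]], b: list[Fraction]
) -> list[Fraction] | None:
    """One exact solution of A·x = b (free variables 0), or None."""
    m, n = len(A), (len(A[0]) if A else 0)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    pivots: list[tuple[int, int]] = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, m) if M[i][c] != 0), None)
        if pivot is None:
            continue
        M[r], M[pivot] = M[pivot], M[r]
        pv = M[r][c]
        M[r] = [v / pv for v in M[r]]
        for i in range(m):
            if i != r and M[i][c] != 0:
                f = M[i][c]
                M[i] = [vi - f * vr for vi, vr in zip(M[i], M[r])]
        pivots.append((r, c))
        r += 1
        if r == m:
            break
    for i in range(r, m):
        if M[i][n] != 0:
            return None
    x = [Fraction(0)] * n
    for row, col in pivots:
        x[col] = M[row][n]
    return x
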
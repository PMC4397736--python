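"""Per-reaction protein costs and the cost-augmented model.

The protein cost of carrying flux J through an enzyme-catalysed reaction is

    J · MW · exp(α · ΔrG'° / RT)

with MW the enzyme molecular weight (kDa) and ΔrG'° the standard Gibbs free
energy of reaction (kcal/mol).  α is fixed at 0.02·RT mol/kcal, so the
thermodynamic factor reduces to exp(0.02 · ΔrG'°) — temperature-independent
— and is applied only to reversible reactions, with the reciprocal factor
exp(−0.02·ΔrG'°) on the backward direction.  Reactions without an associated
enzyme cost nothing.

Because the cost is linear in flux it can be embedded in the stoichiometry:
every enzyme-associated reversible reaction is split into irreversible
forward/backward halves, each producing a pseudo-metabolite
(``protein_cost__x``) at its direction's cost coefficient, and a single sink
reaction (``COST_SINK``) consumes that metabolite.  At steady state the sink
flux equals the total protein cost, so minimizing one LP variable minimizes
the cost of the whole distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from statistics import median

from .model_io import (
    CostTable,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

#: exp(ALPHA_SCALED · ΔrG'°[kcal/mol]) is the thermodynamic penalty; the
#: value absorbs α = 0.02·RT mol/kcal, cancelling the RT denominator.
ALPHA_SCALED_DEFAULT = 0.02

COST_METABOLITE_ID = "protein_cost__x"
COST_COMPARTMENT = "cost"
COST_SINK_ID = "COST_SINK"
FORWARD_SUFFIX = "__f"
BACKWARD_SUFFIX = "__b"

COST_TYPES = ("uniform", "mw", "thermo", "combined")


def thermo_factor(
    dG0: float,
    direction: str = "forward",
    reversible: bool = True,
    alpha_scaled: float = ALPHA_SCALED_DEFAULT,
) -> float:
    """Thermodynamic cost factor for one direction of a reaction.

    Reversible reactions pay exp(+α'·ΔrG'°) forward and the reciprocal
    exp(−α'·ΔrG'°) backward (α' = ``alpha_scaled``, per kcal/mol); the
    penalty is applied only to reversible reactions, so irreversible ones
    get factor 1.
    """
    if not math.isfinite(dG0):
        raise ValueError(f"non-finite dG0: {dG0!r}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward/backward, got {direction!r}")
    if not reversible:
        return 1.0
    sign = 1.0 if direction == "forward" else -1.0
    return math.exp(sign * alpha_scaled * dG0)


def impute_missing_weights(costs: CostTable) -> CostTable:
    """Fill missing enzyme molecular weights with the median of known ones.

    Even-count median is the mean of the two central values.  Returns a new
    table; entries gain ``mw_imputed=True``.
    """
    known = [
        e.mw
        for e in costs.entries.values()
        if e.enzyme_associated and e.mw is not None
    ]
    missing = [
        rid
        for rid, e in costs.entries.items()
        if e.enzyme_associated and e.mw is None
    ]
    if not missing:
        return costs
    if not known:
        raise ValueError("cannot impute molecular weights: no known values")
    med = float(median(known))
    out = costs.copy()
    for rid in missing:
        out.entries[rid] = replace(out.entries[rid], mw=med, mw_imputed=True)
    return out


@dataclass(frozen=True)
class DirectionCost:
    """Cost coefficients for the usable directions of one reaction.

    ``backward`` is None for irreversible reactions.
    """

    forward: float
    backward: float | None


@dataclass
class CostCoefficients:
    per_reaction: dict[str, DirectionCost]
    cost_type: str

    def __getitem__(self, rxn_id: str) -> DirectionCost:
        return self.per_reaction[rxn_id]


def build_cost_coefficients(
    model: MetabolicModel,
    costs: CostTable,
    cost_type: str = "combined",
    alpha_scaled: float = ALPHA_SCALED_DEFAULT,
) -> CostCoefficients:
    """Per-direction cost coefficients for one of the four cost functions.

    ``"mw"`` charges molecular weight alone, ``"thermo"`` the thermodynamic
    penalty alone, ``"combined"`` their product, and ``"uniform"`` charges 1
    per unit flux through every enzyme-associated direction (a pFBA-style
    minimization of total enzymatic flux).  Non-enzymatic reactions always
    cost zero.

    The cost-table ``enzyme`` flag takes precedence over the model's
    gene-association flag; reactions absent from the table are treated as
    non-enzymatic.
    """
    if cost_type not in COST_TYPES:
        raise ValueError(f"cost_type must be one of {COST_TYPES}, got {cost_type!r}")
    missing: list[str] = []
    per: dict[str, DirectionCost] = {}
    for rxn in model.reactions:
        entry = costs.entries.get(rxn.id)
        enzyme = entry.enzyme_associated if entry is not None else False
        if not enzyme:
            per[rxn.id] = DirectionCost(0.0, 0.0 if rxn.reversible else None)
            continue
        if cost_type in ("mw", "combined") and entry.mw is None:
            missing.append(rxn.id)
            continue
        if cost_type == "uniform":
            fwd, bwd = 1.0, 1.0
        else:
            mw = entry.mw if cost_type in ("mw", "combined") else 1.0
            tf = thermo_factor(entry.dG0, "forward", rxn.reversible, alpha_scaled)
            tb = thermo_factor(entry.dG0, "backward", rxn.reversible, alpha_scaled)
            if cost_type == "mw":
                tf = tb = 1.0
            fwd, bwd = mw * tf, mw * tb
        per[rxn.id] = DirectionCost(fwd, bwd if rxn.reversible else None)
    if missing:
        raise ValueError(
            "enzyme-associated reactions missing molecular weights "
            f"(run impute_missing_weights first): {sorted(missing)}"
        )
    return CostCoefficients(per_reaction=per, cost_type=cost_type)


@dataclass
class CostAugmentedModel:
    """Split-reaction model carrying the cost pseudo-metabolite and sink.

    ``split_map`` sends each original reaction id to its augmented column
    ids ``(forward_id, backward_id_or_None)``; unsplit reactions map to
    ``(own_id, None)``.
    """

    base: MetabolicModel
    original: MetabolicModel
    split_map: dict[str, tuple[str, str | None]]
    cost_metabolite_id: str = COST_METABOLITE_ID
    cost_sink_id: str = COST_SINK_ID
    coefficients: CostCoefficients | None = None

    def net_fluxes(self, split_fluxes: dict[str, float]) -> dict[str, float]:
        """Map augmented-model fluxes back to net fluxes on original reactions."""
        net: dict[str, float] = {}
        for rxn_id, (fwd, bwd) in self.split_map.items():
            v = split_fluxes.get(fwd, 0.0)
            if bwd is not None:
                v -= split_fluxes.get(bwd, 0.0)
            net[rxn_id] = v
        return net

    def total_cost(self, split_fluxes: dict[str, float]) -> float:
        return split_fluxes.get(self.cost_sink_id, 0.0)


def augment_model(
    model: MetabolicModel, coeffs: CostCoefficients
) -> CostAugmentedModel:
    """Embed protein costs into the stoichiometry.

    Enzyme-associated reversible reactions become two irreversible halves
    (``<id>__f`` with bounds [0, ub], ``<id>__b`` with bounds [0, −lb]),
    each producing the cost metabolite at its direction's coefficient;
    irreversible enzyme reactions gain the cost product in place.
    Non-enzymatic reactions pass through untouched.  A single sink
    (``COST_SINK``: cost metabolite → ∅, bounds [0, ∞)) closes the balance,
    so its steady-state flux equals the total protein cost.
    """
    existing = set(model.reaction_ids) | set(model.metabolite_ids)
    if COST_METABOLITE_ID in existing or COST_SINK_ID in existing:
        raise ModelValidationError(
            f"id collision: model already defines {COST_METABOLITE_ID!r} or "
            f"{COST_SINK_ID!r}"
        )
    new_reactions: list[Reaction] = []
    split_map: dict[str, tuple[str, str | None]] = {}
    for rxn in model.reactions:
        dc = coeffs[rxn.id]
        enzymatic = dc.forward > 0 or (dc.backward or 0.0) > 0
        if not enzymatic:
            new_reactions.append(rxn.copy())
            split_map[rxn.id] = (rxn.id, None)
            continue
        if rxn.reversible:
            fwd_id, bwd_id = rxn.id + FORWARD_SUFFIX, rxn.id + BACKWARD_SUFFIX
            if fwd_id in existing or bwd_id in existing:
                raise ModelValidationError(
                    f"generated id collision for reaction {rxn.id!r}"
                )
            fwd_stoich = dict(rxn.stoichiometry)
            fwd_stoich[COST_METABOLITE_ID] = dc.forward
            bwd_stoich = {m: -c for m, c in rxn.stoichiometry.items()}
            bwd_stoich[COST_METABOLITE_ID] = dc.backward
            new_reactions.append(
                Reaction(fwd_id, fwd_stoich, 0.0, rxn.upper_bound,
                         enzyme_associated=True, name=rxn.name)
            )
            new_reactions.append(
                Reaction(bwd_id, bwd_stoich, 0.0, -rxn.lower_bound,
                         enzyme_associated=True, name=rxn.name)
            )
            split_map[rxn.id] = (fwd_id, bwd_id)
        else:
            stoich = dict(rxn.stoichiometry)
            stoich[COST_METABOLITE_ID] = dc.forward
            new_reactions.append(
                Reaction(rxn.id, stoich, max(rxn.lower_bound, 0.0), rxn.upper_bound,
                         enzyme_associated=True, name=rxn.name)
            )
            split_map[rxn.id] = (rxn.id, None)
    mets = list(model.metabolites) + [
        Metabolite(id=COST_METABOLITE_ID, compartment=COST_COMPARTMENT,
                   name="protein cost pseudo-metabolite")
    ]
    new_reactions.append(
        Reaction(COST_SINK_ID, {COST_METABOLITE_ID: -1.0}, 0.0, math.inf,
                 enzyme_associated=False, name="protein cost sink")
    )
    # a split objective reaction is tracked through its forward half
    objective_id = split_map[model.objective_id][0]
    aug = MetabolicModel(
        metabolites=mets,
        reactions=new_reactions,
        objective_id=objective_id,
        id=model.id + "_cost",
    )
    return CostAugmentedModel(
        base=aug, original=model, split_map=split_map, coefficients=coeffs
    )
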
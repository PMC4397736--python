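"""Currency removal, exact ray enumeration, imbalance and scoring."""

import math
from fractions import Fraction

import numpy as np
import pytest

from corso.fixtures import GLYCOLYSIS_CURRENCY, make_loop_fixture
from corso.fundamental_pathways import (
    FundamentalPathway,
    annotate_imbalance,
    atp_potential,
    carrier_conversion,
    enumerate_pathways,
    extreme_rays,
    full_model_imbalance,
    metabolite_base_name,
    pareto_classify,
    recover_balancing_fluxes,
    reduce_model,
    split_columns,
)
from corso.model_io import MetabolicModel, Metabolite, Reaction

from oracles import in_cone, support_minimal_rays


# -- currency removal ------------------------------------------------------


def test_base_name_handles_both_compartment_styles():
    assert metabolite_base_name("atp_c", "c") == "atp"
    assert metabolite_base_name("glc__D[e]", "e") == "glc__D"
    assert metabolite_base_name("weird", "c") == "weird"


def test_glycolysis_currency_removal(glycolysis):
    model, _ = glycolysis
    red = reduce_model(model, GLYCOLYSIS_CURRENCY)
    assert set(red.removed_reactions) == {"EX_h_e", "ATPM", "ATPS4r", "Ht"}
    removed = set(red.removed_metabolites)
    assert {"atp_c", "adp_c", "pi_c", "h_c", "h_e", "h2o_c", "nad_c",
            "nadh_c"} == removed
    for rxn in red.base.reactions:
        assert not set(rxn.stoichiometry) & removed
    assert not [w for w in red.warnings if w.kind == "sink_or_source"]


def test_absent_currency_is_warned_noop(glycolysis):
    model, _ = glycolysis
    red = reduce_model(model, ["coa"])
    assert red.removed_metabolites == []
    assert [w.kind for w in red.warnings] == ["absent_currency"]
    assert len(red.base.reactions) == len(model.reactions)


def test_reaction_turned_pure_source_is_warned():
    model = MetabolicModel(
        metabolites=[Metabolite("a_c", "c"), Metabolite("b_c", "c"),
                     Metabolite("c_c", "c")],
        reactions=[
            Reaction("R1", {"a_c": -1, "b_c": -1, "c_c": 1}, 0, 10),
            Reaction("EX_c", {"c_c": -1}, 0, 10),
        ],
        objective_id="EX_c",
    )
    # removing one substrate keeps R1 (b→c): no warning
    red1 = reduce_model(model, ["a"])
    assert not [w for w in red1.warnings if w.kind == "sink_or_source"]
    # removing both substrates leaves a pure source of c
    red2 = reduce_model(model, ["a", "b"])
    warned = [w for w in red2.warnings if w.kind == "sink_or_source"]
    assert [w.subject for w in warned] == ["R1"]


# -- enumeration -----------------------------------------------------------


def _model(mets, rxns, objective):
    return MetabolicModel(
        metabolites=[Metabolite(m, "c") for m in mets],
        reactions=[Reaction(rid, st, lb, ub) for rid, st, lb, ub in rxns],
        objective_id=objective,
    )


def test_single_chain_yields_one_pathway():
    model = _model(
        ["a_c", "b_c"],
        [("EX_a", {"a_c": -1}, -10, 0),
         ("AB", {"a_c": -1, "b_c": 1}, 0, 10),
         ("EX_b", {"b_c": -1}, 0, 10)],
        "EX_b",
    )
    pws = enumerate_pathways(reduce_model(model, []))
    assert len(pws) == 1
    assert not pws[0].is_internal_loop


def test_diamond_yields_two_pathways():
    model = _model(
        ["a_c", "b_c"],
        [("EX_a", {"a_c": -1}, -10, 0),
         ("r1", {"a_c": -1, "b_c": 1}, 0, 10),
         ("r2", {"a_c": -1, "b_c": 1}, 0, 10),
         ("EX_b", {"b_c": -1}, 0, 10)],
        "EX_b",
    )
    pws = enumerate_pathways(reduce_model(model, []))
    assert len(pws) == 2
    supports = {frozenset(k for k in p.net_flux) for p in pws}
    assert supports == {frozenset({"EX_a", "r1", "EX_b"}),
                        frozenset({"EX_a", "r2", "EX_b"})}


def test_two_cycles_of_reversible_reactions_are_dropped():
    model = _model(
        ["a_c", "b_c"],
        [("EX_a", {"a_c": -1}, -10, 0),
         ("AB", {"a_c": -1, "b_c": 1}, -10, 10),
         ("EX_b", {"b_c": -1}, 0, 10)],
        "EX_b",
    )
    pws = enumerate_pathways(reduce_model(model, []))
    assert len(pws) == 1  # the forward∘backward cycle is not reported


def test_rays_are_integer_scaled_and_exactly_balanced(glycolysis):
    model, _ = glycolysis
    red = reduce_model(model, GLYCOLYSIS_CURRENCY)
    cols = {c.id: c for c in split_columns(red.base)}
    for p in enumerate_pathways(red):
        for v in p.flux.values():
            assert v.denominator == 1 and v > 0
        # S_reduced·v = 0 exactly, in rational arithmetic
        balance: dict[str, Fraction] = {}
        for col_id, v in p.flux.items():
            for met, coef in cols[col_id].stoichiometry.items():
                balance[met] = balance.get(met, Fraction(0)) + coef * v
        assert all(val == 0 for val in balance.values())


def test_size_guard_refuses_large_networks(glycolysis):
    model, _ = glycolysis
    red = reduce_model(model, GLYCOLYSIS_CURRENCY)
    with pytest.raises(ValueError, match="split columns"):
        enumerate_pathways(red, max_columns=4)


def test_internal_loop_detection():
    model, _ = make_loop_fixture(seed=0)
    pws = enumerate_pathways(reduce_model(model, []))
    loops = [p for p in pws if p.is_internal_loop]
    assert len(loops) == 1
    assert set(loops[0].net_flux) == {"L1", "L2", "L3"}
    # removing one loop reaction kills the cycle
    pruned = MetabolicModel(
        model.metabolites,
        [r for r in model.reactions if r.id != "L3"],
        model.objective_id,
    )
    pws2 = enumerate_pathways(reduce_model(pruned, []))
    assert not [p for p in pws2 if p.is_internal_loop]


def test_loop_carries_no_flux_in_cost_minimal_solution():
    from corso.corso_solver import solve_corso
    from corso.cost_model import augment_model, build_cost_coefficients
    from corso.fixtures import make_loop_fixture

    model, costs = make_loop_fixture(seed=0)
    aug = augment_model(model, build_cost_coefficients(model, costs, "combined"))
    sol = solve_corso(aug, fraction=1.0)
    assert sol.net_fluxes["L1"] == pytest.approx(0.0, abs=1e-9)


def test_enumeration_matches_exhaustive_oracle_small():
    """Double description equals brute-force support enumeration on a
    hand-made branched network."""
    model = _model(
        ["a_c", "b_c", "c_c"],
        [("EX_a", {"a_c": -1}, -10, 0),
         ("r1", {"a_c": -1, "b_c": 1}, -10, 10),
         ("r2", {"b_c": -1, "c_c": 1}, 0, 10),
         ("r3", {"a_c": -1, "c_c": 1}, 0, 10),
         ("EX_c", {"c_c": -1}, 0, 10)],
        "EX_c",
    )
    red = reduce_model(model, [])
    cols = split_columns(red.base)
    midx = {m.id: i for i, m in enumerate(red.base.metabolites)}
    rows = [dict() for _ in midx]
    for j, col in enumerate(cols):
        for met, coef in col.stoichiometry.items():
            rows[midx[met]][j] = coef
    expected = support_minimal_rays(rows, len(cols))
    got = set(extreme_rays(rows, len(cols)))
    assert got == expected


def test_feasible_reduced_flux_is_conic_combination(glycolysis):
    """Conic generation: any feasible reduced-network flux lies in the
    cone spanned by the enumerated rays."""
    from scipy.optimize import linprog

    model, _ = glycolysis
    red = reduce_model(model, GLYCOLYSIS_CURRENCY)
    cols = split_columns(red.base)
    midx = {m.id: i for i, m in enumerate(red.base.metabolites)}
    A = np.zeros((len(midx), len(cols)))
    for j, col in enumerate(cols):
        for met, coef in col.stoichiometry.items():
            A[midx[met], j] = float(coef)
    rng = np.random.default_rng(7)
    rays = []
    col_ids = [c.id for c in cols]
    for p in enumerate_pathways(red, max_columns=100):
        rays.append(tuple(p.flux.get(cid, Fraction(0)) for cid in col_ids))
    # add back the forward∘backward two-cycles, legitimate cone members
    seen = set()
    for c in cols:
        if c.reaction_id not in seen and c.id.endswith("__b"):
            seen.add(c.reaction_id)
            ray = tuple(
                Fraction(1) if cc.reaction_id == c.reaction_id else Fraction(0)
                for cc in cols
            )
            rays.append(ray)
    for _ in range(3):
        c_obj = -rng.random(len(cols))
        res = linprog(c_obj, A_eq=A, b_eq=np.zeros(A.shape[0]),
                      bounds=[(0, 5)] * len(cols), method="highs")
        assert res.success
        assert in_cone(rays, res.x)


# -- imbalance -------------------------------------------------------------


def test_glycolysis_pathway_imbalance(glycolysis):
    model, _ = glycolysis
    red = reduce_model(model, GLYCOLYSIS_CURRENCY)
    (p,) = enumerate_pathways(red)
    annotate_imbalance(p, model)
    scaled = p.scaled_net_flux("EX_glc__D_e")
    assert scaled["EX_lac__D_e"] == Fraction(2)
    glc = abs(p.net_flux["EX_glc__D_e"])
    assert p.imbalance["atp_c"] / glc == Fraction(2)
    assert p.imbalance["adp_c"] / glc == Fraction(-2)
    assert "nad_c" not in p.imbalance  # redox-balanced backbone


def test_balanced_pathway_has_empty_imbalance():
    model = _model(
        ["a_c", "b_c"],
        [("EX_a", {"a_c": -1}, -10, 0),
         ("AB", {"a_c": -1, "b_c": 1}, 0, 10),
         ("EX_b", {"b_c": -1}, 0, 10)],
        "EX_b",
    )
    (p,) = enumerate_pathways(reduce_model(model, []))
    annotate_imbalance(p, model)
    assert p.imbalance == {}


def test_hand_computed_matrix_vector_imbalance():
    model = _model(
        ["a_c", "b_c", "x_c"],
        [("R1", {"a_c": -2, "b_c": 1, "x_c": 3}, 0, 10),
         ("R2", {"b_c": -1, "a_c": 2}, 0, 10)],
        "R1",
    )
    flux = {"R1": Fraction(2), "R2": Fraction(1)}
    # a: -4 + 2 = -2 ; b: 2 - 1 = 1 ; x: 6
    assert full_model_imbalance(model, flux) == {
        "a_c": Fraction(-2), "b_c": Fraction(1), "x_c": Fraction(6)
    }
    with pytest.raises(KeyError):
        full_model_imbalance(model, {"nope": Fraction(1)})


# -- carrier conversion and ATP potential ---------------------------------


def test_etc_nadh_yield_and_cost(etc_aug):
    """Hand LP: 1 NADH → 8 periplasmic protons → 2 ATP; the cost is one
    dehydrogenase unit plus two synthase units."""
    y, c = carrier_conversion(etc_aug, "nadh_c", atp_drain_id="ATPM")
    assert y == pytest.approx(2.0)
    expected = 80.0 + 2 * 530.0 * math.exp(0.02 * 3.0)
    assert c == pytest.approx(expected, rel=1e-6)


def test_atp_converts_to_itself_for_free(etc_aug):
    assert carrier_conversion(etc_aug, "atp_c", atp_drain_id="ATPM") == (1.0, 0.0)


def test_disconnected_carrier_returns_zero_with_warning(glycolysis_aug, caplog):
    # no respiratory chain in the glycolysis fixture: NADH cannot drive ATP
    with caplog.at_level("WARNING"):
        y, c = carrier_conversion(glycolysis_aug, "nadh_c", atp_drain_id="ATPM")
    assert (y, c) == (0.0, 0.0)
    assert any("cannot drive" in r.message for r in caplog.records)


def _bare_pathway(imbalance):
    return FundamentalPathway(
        id="P", flux={}, columns={}, is_internal_loop=False,
        net_flux={}, imbalance={k: Fraction(v) for k, v in imbalance.items()},
    )


def test_atp_potential_formula(glycolysis, glycolysis_aug):
    model, _ = glycolysis
    coeffs = glycolysis_aug.coefficients
    p = _bare_pathway({"atp_c": 2})
    atp_potential(p, {}, [], coeffs, model)
    assert p.atp_potential == pytest.approx(2.0)

    p2 = _bare_pathway({"atp_c": 2, "nadh_c": 2})
    atp_potential(p2, {"nadh": (2.0, 5.0)}, ["nadh"], coeffs, model)
    assert p2.atp_potential == pytest.approx(2 + 2 * 2)
    assert p2.total_cost == pytest.approx(2 * 5.0)
    assert p2.cost_per_atp == pytest.approx(10.0 / 6.0)


def test_consumed_carrier_subtracts_symmetrically(glycolysis, glycolysis_aug):
    model, _ = glycolysis
    p = _bare_pathway({"atp_c": 4, "nadh_c": -1})
    atp_potential(p, {"nadh": (2.0, 5.0)}, ["nadh"],
                  glycolysis_aug.coefficients, model)
    assert p.atp_potential == pytest.approx(4 - 2)
    assert p.total_cost == pytest.approx(0.0)  # no surplus to convert


def test_nonpositive_potential_gives_infinite_cost_per_atp(
    glycolysis, glycolysis_aug
):
    model, _ = glycolysis
    p = _bare_pathway({})
    atp_potential(p, {}, [], glycolysis_aug.coefficients, model)
    assert p.atp_potential == 0.0
    assert math.isinf(p.cost_per_atp)


def test_missing_carrier_conversion_is_error(glycolysis, glycolysis_aug):
    model, _ = glycolysis
    p = _bare_pathway({"atp_c": 1})
    with pytest.raises(KeyError):
        atp_potential(p, {}, ["nadh"], glycolysis_aug.coefficients, model)


# -- Pareto classification -------------------------------------------------


def _scored(atp, cpa, loop=False):
    p = FundamentalPathway(id=f"{atp}/{cpa}", flux={}, columns={},
                           is_internal_loop=loop)
    p.atp_potential, p.cost_per_atp = atp, cpa
    return p


def test_dominating_pathway_is_single_op():
    a, b = _scored(10, 1.0), _scored(5, 2.0)
    pareto_classify([a, b], margin=0.1)
    assert a.classification == "OP"
    assert b.classification == "other"


def test_axis_specialists_are_both_op():
    cheap, productive = _scored(5, 1.0), _scored(10, 3.0)
    pareto_classify([cheap, productive])
    assert {cheap.classification, productive.classification} == {"OP"}


def test_near_frontier_pathway_is_nop():
    op = _scored(10, 1.0)
    near = _scored(9.5, 1.05)   # within 10% on both axes
    far = _scored(2, 10.0)
    pareto_classify([op, near, far], margin=0.1)
    assert op.classification == "OP"
    assert near.classification == "NOP"
    assert far.classification == "other"


def test_loops_and_unscored_pathways_stay_other():
    loop = _scored(10, 1.0, loop=True)
    ok = _scored(5, 2.0)
    pareto_classify([loop, ok])
    assert loop.classification == "other"
    assert ok.classification == "OP"
    assert pareto_classify([]) == []


# -- reconstruction property ----------------------------------------------


def test_adding_back_removed_loops_restores_exact_balance(glycolysis):
    model, _ = glycolysis
    red = reduce_model(model, GLYCOLYSIS_CURRENCY)
    (p,) = enumerate_pathways(red)
    annotate_imbalance(p, model)
    balancing = recover_balancing_fluxes(p, model, red)
    assert set(balancing) <= set(red.removed_reactions)
    combined = dict(p.net_flux)
    for rid, v in balancing.items():
        combined[rid] = combined.get(rid, Fraction(0)) + v
    assert full_model_imbalance(model, combined) == {}
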
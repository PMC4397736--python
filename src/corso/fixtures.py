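"""Deterministic toy models and cost tables.

Three hand-built networks cover the behaviors the method is about, without
any external model downloads:

* a mini-glycolysis network converting 1 glucose to 2 lactate with a net
  gain of 2 ATP, plus the classic balancing set (ATP maintenance
  hydrolysis, an ATP synthase, a proton leak) whose loops multiply plain
  extreme pathways but collapse to a single fundamental pathway once
  currency metabolites are removed;
* a two-route overflow network with a high-yield/expensive and a
  low-yield/cheap pathway to biomass, exhibiting the cost/yield switch at
  a derivable objective fraction;
* a loop network containing an internal (type III) cycle that carries no
  exchange flux.

Randomized small networks (seeded, bit-reproducible) feed the brute-force
oracle suites.  All fixtures can be emitted as files (BiGG-style JSON +
cost/medium TSVs) so command-line paths are exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import (
    CostEntry,
    CostTable,
    MetabolicModel,
    Metabolite,
    Reaction,
    write_cost_table,
    write_model,
)

logger = logging.getLogger(__name__)

#: Currency metabolites present in the glycolysis fixture (base names).
GLYCOLYSIS_CURRENCY = ("atp", "adp", "pi", "h", "h2o", "nad", "nadh")


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def _met(mid: str, comp: str, name: str = "") -> Metabolite:
    return Metabolite(id=mid, compartment=comp, name=name)


def _rxn(rid, stoich, lb, ub, enzyme=False, name="") -> Reaction:
    return Reaction(rid, stoich, lb, ub, enzyme_associated=enzyme, name=name)


# ---------------------------------------------------------------------------
# mini-glycolysis
# ---------------------------------------------------------------------------


def make_glycolysis_fixture() -> tuple[MetabolicModel, CostTable]:
    """Glucose → 2 lactate glycolysis with its currency balancing set.

    Standard glycolytic stoichiometry with PTS glucose uptake and D-lactate
    dehydrogenase: per glucose, the backbone produces 2 lactate and a net
    +2 ATP (PFK spends one, PGK recovers two, PYK one; the PTS spends PEP
    rather than ATP).  The balancing set — ATP maintenance hydrolysis
    (``ATPM``, also the energy objective), an ATP synthase (``ATPS4r``)
    and a proton leak (``Ht``) — closes the ATP/proton/water books in the
    full model and forms the loops that inflate plain extreme-pathway
    counts.
    """
    e, c = "e", "c"
    mets = [
        _met("glc__D_e", e, "D-glucose"),
        _met("lac__D_e", e, "D-lactate"),
        _met("h_e", e, "proton"),
        _met("g6p_c", c, "glucose 6-phosphate"),
        _met("f6p_c", c, "fructose 6-phosphate"),
        _met("fdp_c", c, "fructose 1,6-bisphosphate"),
        _met("dhap_c", c, "dihydroxyacetone phosphate"),
        _met("g3p_c", c, "glyceraldehyde 3-phosphate"),
        _met("13dpg_c", c, "1,3-bisphosphoglycerate"),
        _met("3pg_c", c, "3-phosphoglycerate"),
        _met("2pg_c", c, "2-phosphoglycerate"),
        _met("pep_c", c, "phosphoenolpyruvate"),
        _met("pyr_c", c, "pyruvate"),
        _met("lac__D_c", c, "D-lactate"),
        _met("atp_c", c, "ATP"),
        _met("adp_c", c, "ADP"),
        _met("pi_c", c, "phosphate"),
        _met("h_c", c, "proton"),
        _met("h2o_c", c, "water"),
        _met("nad_c", c, "NAD+"),
        _met("nadh_c", c, "NADH"),
    ]
    B = 1000.0
    rxns = [
        _rxn("EX_glc__D_e", {"glc__D_e": -1}, -10.0, 0.0, name="glucose exchange"),
        _rxn("EX_lac__D_e", {"lac__D_e": -1}, 0.0, B, name="lactate exchange"),
        # secretion only: free proton uptake would drive the synthase as a
        # perpetual ATP source
        _rxn("EX_h_e", {"h_e": -1}, 0.0, B, name="proton exchange"),
        _rxn("GLCpts", {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1},
             0.0, B, enzyme=True, name="glucose PTS"),
        _rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, -B, B, enzyme=True,
             name="phosphoglucose isomerase"),
        _rxn("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1},
             0.0, B, enzyme=True, name="phosphofructokinase"),
        _rxn("FBA", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, -B, B, enzyme=True,
             name="fructose-bisphosphate aldolase"),
        _rxn("TPI", {"dhap_c": -1, "g3p_c": 1}, -B, B, enzyme=True,
             name="triose-phosphate isomerase"),
        _rxn("GAPD", {"g3p_c": -1, "nad_c": -1, "pi_c": -1,
                      "13dpg_c": 1, "nadh_c": 1, "h_c": 1},
             -B, B, enzyme=True, name="GAP dehydrogenase"),
        _rxn("PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1},
             -B, B, enzyme=True, name="phosphoglycerate kinase"),
        _rxn("PGM", {"3pg_c": -1, "2pg_c": 1}, -B, B, enzyme=True,
             name="phosphoglycerate mutase"),
        _rxn("ENO", {"2pg_c": -1, "pep_c": 1, "h2o_c": 1}, -B, B, enzyme=True,
             name="enolase"),
        _rxn("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
             0.0, B, enzyme=True, name="pyruvate kinase"),
        _rxn("LDH_D", {"pyr_c": -1, "nadh_c": -1, "h_c": -1,
                       "lac__D_c": 1, "nad_c": 1},
             -B, B, enzyme=True, name="D-lactate dehydrogenase"),
        _rxn("LACt", {"lac__D_c": -1, "lac__D_e": 1}, -B, B,
             name="lactate transport"),
        _rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
             0.0, B, name="ATP maintenance hydrolysis"),
        _rxn("ATPS4r", {"adp_c": -1, "pi_c": -1, "h_e": -4,
                        "atp_c": 1, "h2o_c": 1, "h_c": 3},
             -B, B, enzyme=True, name="ATP synthase"),
        # leak runs down-gradient only; a reversible leak would let the
        # synthase recycle its own protons and inflate gross ATPM flux
        _rxn("Ht", {"h_e": -1, "h_c": 1}, 0.0, B, name="proton leak"),
    ]
    model = MetabolicModel(mets, rxns, objective_id="ATPM", id="mini_glycolysis")
    # representative molecular weights (kDa) and ΔrG'° (kcal/mol)
    enzyme_data = {
        "GLCpts": (63.6, -4.0),
        "PGI": (61.5, 0.6),
        "PFK": (34.8, -3.4),
        "FBA": (39.1, 5.3),
        "TPI": (27.0, 1.8),
        "GAPD": (35.5, 1.5),
        "PGK": (41.1, -4.4),
        "PGM": (56.0, 1.0),
        "ENO": (45.7, -0.9),
        "PYK": (51.0, -7.5),
        "LDH_D": (32.5, -6.0),
        "ATPS4r": (530.0, 3.0),
    }
    entries = {}
    for rxn in rxns:
        if rxn.id in enzyme_data:
            mw, dg = enzyme_data[rxn.id]
            entries[rxn.id] = CostEntry(mw=mw, dG0=dg, enzyme_associated=True)
        else:
            entries[rxn.id] = CostEntry(mw=None, dG0=0.0, enzyme_associated=False)
    return model, CostTable(entries)


# ---------------------------------------------------------------------------
# overflow metabolism
# ---------------------------------------------------------------------------


def make_overflow_fixture(
    yield_hi: float = 2.0,
    yield_lo: float = 1.0,
    cost_hi: float = 10.0,
    cost_lo: float = 3.0,
    glc_bound: float = 10.0,
) -> tuple[MetabolicModel, CostTable]:
    """Two parallel glucose→biomass routes trading yield against cost.

    The high-yield route makes ``yield_hi`` biomass precursor per glucose
    at enzyme cost ``cost_hi`` per unit flux; the low-yield route
    ``yield_lo`` at ``cost_lo``.  When the cost per biomass favors the
    cheap route (cost_hi/yield_hi > cost_lo/yield_lo) the cost-minimal
    solution runs entirely through it below the switch fraction
    f* = yield_lo/yield_hi, while at fraction 1 glucose limitation forces
    the high-yield route.
    """
    if not (yield_hi > yield_lo > 0):
        raise ValueError("need yield_hi > yield_lo > 0")
    if not cost_hi / yield_hi > cost_lo / yield_lo:
        logger.warning(
            "cost per biomass does not favor the low-yield route; "
            "no cost/yield switch exists"
        )
    B = 1000.0
    mets = [_met("glc_e", "e", "glucose"), _met("prec_c", "c", "biomass precursor")]
    rxns = [
        _rxn("EX_glc", {"glc_e": -1}, -abs(glc_bound), 0.0),
        _rxn("PATH_HI", {"glc_e": -1, "prec_c": yield_hi}, 0.0, B, enzyme=True,
             name="high-yield route"),
        _rxn("PATH_LO", {"glc_e": -1, "prec_c": yield_lo}, 0.0, B, enzyme=True,
             name="low-yield route"),
        _rxn("BIOMASS", {"prec_c": -1}, 0.0, B, name="biomass drain"),
    ]
    model = MetabolicModel(mets, rxns, objective_id="BIOMASS", id="overflow")
    costs = CostTable(
        {
            "EX_glc": CostEntry(None, 0.0, False),
            "PATH_HI": CostEntry(cost_hi, 0.0, True),
            "PATH_LO": CostEntry(cost_lo, 0.0, True),
            "BIOMASS": CostEntry(None, 0.0, False),
        }
    )
    return model, costs


def overflow_switch_fraction(yield_hi: float = 2.0, yield_lo: float = 1.0) -> float:
    """Analytic switch fraction of the overflow fixture.

    Below f* = yield_lo/yield_hi the glucose budget still allows the whole
    biomass demand through the cheap route; above it the expensive
    high-yield route must carry a growing share.
    """
    return yield_lo / yield_hi


# ---------------------------------------------------------------------------
# internal loop
# ---------------------------------------------------------------------------


def make_loop_fixture(seed: int = 0) -> tuple[MetabolicModel, CostTable]:
    """A linear pathway plus a three-reaction internal cycle.

    The A→B→C→A cycle consumes nothing and touches no exchange, so its
    extreme ray is a type III (internal) loop; enzyme costs on the loop
    reactions make any flux around it strictly wasteful for the solver.
    Molecular weights are drawn reproducibly from ``seed``.
    """
    rng = np.random.default_rng(seed)
    B = 1000.0
    mets = [
        _met("x_e", "e", "substrate"),
        _met("a_c", "c"), _met("b_c", "c"), _met("c_c", "c"),
        _met("bm_e", "e", "biomass"),
    ]
    rxns = [
        _rxn("EX_x", {"x_e": -1}, -10.0, 0.0),
        _rxn("TX", {"x_e": -1, "a_c": 1}, 0.0, B, enzyme=True, name="uptake"),
        _rxn("L1", {"a_c": -1, "b_c": 1}, 0.0, B, enzyme=True),
        _rxn("L2", {"b_c": -1, "c_c": 1}, 0.0, B, enzyme=True),
        _rxn("L3", {"c_c": -1, "a_c": 1}, 0.0, B, enzyme=True),
        _rxn("GROW", {"a_c": -1, "bm_e": 1}, 0.0, B, enzyme=True),
        _rxn("EX_bm", {"bm_e": -1}, 0.0, B),
    ]
    model = MetabolicModel(mets, rxns, objective_id="EX_bm", id="loop")
    entries = {}
    for rxn in rxns:
        if rxn.enzyme_associated:
            mw = float(np.round(rng.uniform(20.0, 80.0), 3))
            dg = float(np.round(rng.uniform(-5.0, 5.0), 3))
            entries[rxn.id] = CostEntry(mw, dg, True)
        else:
            entries[rxn.id] = CostEntry(None, 0.0, False)
    return model, CostTable(entries)


# ---------------------------------------------------------------------------
# toy electron transport chain
# ---------------------------------------------------------------------------


def make_etc_fixture() -> tuple[MetabolicModel, CostTable]:
    """A minimal respiratory chain: NADH → proton gradient → ATP.

    The dehydrogenase pumps 8 protons per NADH; the synthase makes one ATP
    per 4 periplasmic protons, returning 3 to the cytosol, so one NADH
    yields exactly 2 ATP through the maintenance drain.  Used to measure
    energy-carrier → ATP conversion yields and costs.
    """
    B = 1000.0
    mets = [
        _met("nad_c", "c", "NAD+"), _met("nadh_c", "c", "NADH"),
        _met("atp_c", "c", "ATP"), _met("adp_c", "c", "ADP"),
        _met("pi_c", "c", "phosphate"), _met("h2o_c", "c", "water"),
        _met("h_c", "c", "proton"), _met("h_e", "e", "proton"),
    ]
    rxns = [
        # boundary supply of reducing power so the fixture is solvable on
        # its own; conversion measurements close these uptakes anyway
        _rxn("EX_nadh", {"nadh_c": -1}, -10.0, 0.0, name="NADH supply"),
        _rxn("EX_nad", {"nad_c": -1}, 0.0, 10.0, name="NAD+ drain"),
        _rxn("NADHD", {"nadh_c": -1, "h_c": -8, "nad_c": 1, "h_e": 8},
             0.0, B, enzyme=True, name="NADH dehydrogenase (proton pump)"),
        _rxn("ATPS4r", {"adp_c": -1, "pi_c": -1, "h_e": -4,
                        "atp_c": 1, "h2o_c": 1, "h_c": 3},
             -B, B, enzyme=True, name="ATP synthase"),
        _rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
             0.0, B, name="ATP maintenance hydrolysis"),
        _rxn("Ht", {"h_e": -1, "h_c": 1}, 0.0, B, name="proton leak"),
        _rxn("EX_h_e", {"h_e": -1}, 0.0, B, name="proton exchange"),
    ]
    model = MetabolicModel(mets, rxns, objective_id="ATPM", id="toy_etc")
    costs = CostTable(
        {
            "EX_nadh": CostEntry(None, 0.0, False),
            "EX_nad": CostEntry(None, 0.0, False),
            "NADHD": CostEntry(80.0, -16.0, True),
            "ATPS4r": CostEntry(530.0, 3.0, True),
            "ATPM": CostEntry(None, 0.0, False),
            "Ht": CostEntry(None, 0.0, False),
            "EX_h_e": CostEntry(None, 0.0, False),
        }
    )
    return model, costs


# ---------------------------------------------------------------------------
# randomized toys for the oracle suites
# ---------------------------------------------------------------------------


def make_random_toy_model(seed: int) -> tuple[MetabolicModel, CostTable]:
    """A feasible random parallel-route model with ≤ 8 reactions.

    One substrate with a random uptake bound feeds 1–3 routes of random
    yield to a biomass precursor; some routes are reversible or excrete a
    byproduct.  Costs (MW, ΔrG'°) are random but strictly positive, so a
    cost-minimal distribution is well defined.
    """
    rng = np.random.default_rng(seed)
    B = 1000.0
    uptake = float(rng.integers(4, 11))
    n_routes = int(rng.integers(1, 4))
    mets = [_met("s_e", "e", "substrate"), _met("m_c", "c", "precursor")]
    use_byproduct = bool(rng.random() < 0.5)
    if use_byproduct:
        mets.append(_met("w_e", "e", "byproduct"))
    rxns = [_rxn("EX_s", {"s_e": -1}, -uptake, 0.0)]
    entries = {"EX_s": CostEntry(None, 0.0, False)}
    for i in range(n_routes):
        y = float(rng.integers(1, 4))
        stoich = {"s_e": -1.0, "m_c": y}
        if use_byproduct and rng.random() < 0.5:
            stoich["w_e"] = float(rng.integers(1, 3))
        rid = f"R{i}"
        # routes stay irreversible: a reversible route of different yield
        # would form a gain loop and make step-one FBA unbounded
        rxns.append(_rxn(rid, stoich, 0.0, B, enzyme=True))
        entries[rid] = CostEntry(
            mw=float(np.round(rng.uniform(1.0, 20.0), 3)),
            dG0=float(np.round(rng.uniform(-5.0, 5.0), 3)),
            enzyme_associated=True,
        )
    biomass_precursor = "m_c"
    if rng.random() < 0.5:
        # reversible 1:1 isomerization exercises reaction splitting safely
        mets.append(_met("n_c", "c", "isomerized precursor"))
        rxns.append(_rxn("ISO", {"m_c": -1.0, "n_c": 1.0}, -B, B, enzyme=True))
        entries["ISO"] = CostEntry(
            mw=float(np.round(rng.uniform(1.0, 20.0), 3)),
            dG0=float(np.round(rng.uniform(-5.0, 5.0), 3)),
            enzyme_associated=True,
        )
        biomass_precursor = "n_c"
    rxns.append(_rxn("BIOMASS", {biomass_precursor: -1}, 0.0, B))
    entries["BIOMASS"] = CostEntry(None, 0.0, False)
    if use_byproduct:
        rxns.append(_rxn("EX_w", {"w_e": -1}, 0.0, B))
        entries["EX_w"] = CostEntry(None, 0.0, False)
    model = MetabolicModel(mets, rxns, objective_id="BIOMASS",
                           id=f"toy_{seed}")
    return model, CostTable(entries)


def make_random_network(seed: int, n_mets: int = 3, n_rxns: int = 6
                        ) -> MetabolicModel:
    """A random small network for cone-enumeration cross-checks.

    Internal reactions get sparse integer stoichiometry in {−2..2}; each
    metabolite also gets a one-directional exchange column with
    probability ~2/3, keeping the flux cone non-trivial.  About a third of
    internal reactions are reversible to exercise splitting.
    """
    rng = np.random.default_rng(seed)
    B = 1000.0
    mets = [_met(f"m{i}_c", "c") for i in range(n_mets)]
    rxns: list[Reaction] = []
    for j in range(n_rxns):
        stoich: dict[str, float] = {}
        while not stoich or all(v == 0 for v in stoich.values()):
            stoich = {}
            for i in range(n_mets):
                if rng.random() < 0.6:
                    coef = int(rng.integers(-2, 3))
                    if coef:
                        stoich[f"m{i}_c"] = float(coef)
        reversible = bool(rng.random() < 0.3)
        rxns.append(_rxn(f"r{j}", stoich, -B if reversible else 0.0, B))
    for i in range(n_mets):
        if rng.random() < 0.67:
            direction = rng.random() < 0.5
            rxns.append(
                _rxn(f"EX_m{i}", {f"m{i}_c": -1.0},
                     -B if direction else 0.0, 0.0 if direction else B)
            )
    return MetabolicModel(mets, rxns, objective_id=rxns[0].id,
                          id=f"cone_{seed}")


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

_BUILDERS = {
    "glycolysis": lambda: make_glycolysis_fixture(),
    "overflow": lambda: make_overflow_fixture(),
    "loop": lambda: make_loop_fixture(),
    "etc": lambda: make_etc_fixture(),
}


def write_fixture(name: str, outdir: str | Path) -> dict[str, Path]:
    """Emit a named fixture as model.json + costs.tsv + medium.tsv."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_BUILDERS)}")
    model, costs = _BUILDERS[name]()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": outdir / "model.json",
        "costs": outdir / "costs.tsv",
        "medium": outdir / "medium.tsv",
    }
    write_model(model, paths["model"])
    write_cost_table(costs, paths["costs"])
    rows = []
    for rxn in model.exchange_reactions():
        rows.append(
            {
                "exchange_id": rxn.id,
                "uptake_bound": max(0.0, -rxn.lower_bound),
                "secretion_allowed": int(rxn.upper_bound > 0),
            }
        )
    pd.DataFrame(rows, columns=["exchange_id", "uptake_bound",
                                "secretion_allowed"]).to_csv(
        paths["medium"], sep="\t", index=False
    )
    return paths
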
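"""Constraint-based model containers and file I/O.

The in-memory representation is deliberately small: a
:class:`MetabolicModel` is a list of :class:`Metabolite` and
:class:`Reaction` objects plus the id of the biomass (objective) reaction.
The stoichiometric matrix ``S`` (rows = metabolites, columns = reactions)
is derived from the reaction stoichiometries on demand as a scipy sparse
matrix.

Supported input formats:

* BiGG-style JSON — the de-facto interchange dialect for genome-scale
  reconstructions (``metabolites`` / ``reactions`` arrays, per-reaction
  ``metabolites`` stoichiometry maps, ``lower_bound`` / ``upper_bound``,
  ``objective_coefficient``).  Parsed natively; round-trips exactly.
* SBML Level 3 with the FBC package — parsed through COBRApy.

Cost tables (enzyme molecular weight in kDa, standard Gibbs free energy of
reaction in kcal/mol, enzyme-association flag) are tab-separated files with
the fixed header ``reaction_id  mw_kda  dG0_kcal_mol  enzyme``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: Encoding of "arbitrarily large" flux bounds (mmol·gDW⁻¹·h⁻¹ by the usual
#: COBRA convention; units are carried opaquely).
DEFAULT_BOUND = 1000.0

COST_TABLE_COLUMNS = ("reaction_id", "mw_kda", "dG0_kcal_mol", "enzyme")


class FormatError(ValueError):
    """A file did not parse under the named standard."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment (e.g. ``"c"``, ``"e"``)."""

    id: str
    compartment: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: empty compartment")


@dataclass
class Reaction:
    """A (possibly reversible) reaction with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    coefficients are consumed, positive produced.  ``enzyme_associated``
    marks reactions that carry a protein cost downstream.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    enzyme_associated: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        """True iff flux may run in both directions (lb < 0 < ub)."""
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """A reaction touching exactly one metabolite (system boundary)."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            enzyme_associated=self.enzyme_associated,
            name=self.name,
        )


@dataclass
class MetabolicModel:
    """A constraint-based model: S·v = 0 with per-reaction flux bounds."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def S(self) -> sparse.csc_matrix:
        """Sparse stoichiometric matrix (rows = metabolites, cols = reactions)."""
        midx = self.metabolite_index()
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                rows.append(midx[met_id])
                cols.append(j)
                data.append(coeff)
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
        if self.objective_id not in known and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            id=self.id,
        )


# ---------------------------------------------------------------------------
# cost tables
# ---------------------------------------------------------------------------


@dataclass
class CostEntry:
    """Per-reaction cost data: enzyme MW (kDa) and ΔrG'° (kcal/mol).

    ``mw`` is None while a missing molecular weight awaits median imputation;
    ``mw_imputed`` records imputation provenance.
    """

    mw: float | None
    dG0: float
    enzyme_associated: bool
    mw_imputed: bool = False


@dataclass
class CostTable:
    entries: dict[str, CostEntry] = field(default_factory=dict)

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.entries

    def __getitem__(self, rxn_id: str) -> CostEntry:
        return self.entries[rxn_id]

    def copy(self) -> "CostTable":
        return CostTable({k: replace(v) for k, v in self.entries.items()})


def load_cost_table(path: str | Path) -> CostTable:
    """Read a tab-separated cost table.

    Expected header (exactly): ``reaction_id  mw_kda  dG0_kcal_mol  enzyme``.
    Empty ``mw_kda`` fields are flagged for imputation; empty ``dG0_kcal_mol``
    fields are treated as 0 (thermodynamic penalty factor 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
    if tuple(df.columns) != COST_TABLE_COLUMNS:
        raise FormatError(
            f"cost table {path}: header must be {COST_TABLE_COLUMNS}, "
            f"got {tuple(df.columns)}"
        )
    if df["reaction_id"].duplicated().any():
        dupes = sorted(df.loc[df["reaction_id"].duplicated(), "reaction_id"])
        raise FormatError(f"cost table {path}: duplicate reaction ids {dupes}")
    entries: dict[str, CostEntry] = {}
    for row in df.itertuples(index=False):
        mw = None if pd.isna(row.mw_kda) else float(row.mw_kda)
        if mw is not None and mw < 0:
            raise FormatError(
                f"cost table {path}: negative molecular weight for {row.reaction_id}"
            )
        dG0 = 0.0 if pd.isna(row.dG0_kcal_mol) else float(row.dG0_kcal_mol)
        entries[str(row.reaction_id)] = CostEntry(
            mw=mw, dG0=dG0, enzyme_associated=bool(int(row.enzyme))
        )
    return CostTable(entries)


def write_cost_table(costs: CostTable, path: str | Path) -> None:
    rows = []
    for rxn_id, e in costs.entries.items():
        rows.append(
            {
                "reaction_id": rxn_id,
                "mw_kda": "" if e.mw is None else e.mw,
                "dG0_kcal_mol": e.dG0,
                "enzyme": int(e.enzyme_associated),
            }
        )
    pd.DataFrame(rows, columns=list(COST_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# model readers / writers
# ---------------------------------------------------------------------------


def read_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Read a constraint-based model from disk.

    ``format`` is ``"json"`` (BiGG-style dialect, parsed natively) or
    ``"sbml"`` (Level 3 + FBC, parsed through COBRApy).  Exchange reactions
    are detected structurally (single-metabolite columns) and
    ``enzyme_associated`` is set from gene-association presence; a cost
    table, when supplied downstream, overrides that flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        return _read_json_model(path)
    if format == "sbml":
        return _read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_json_model(path: Path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise FormatError(f"{path}: missing top-level {key!r} array")
    mets = []
    for m in doc["metabolites"]:
        if "id" not in m:
            raise FormatError(f"{path}: metabolite entry without id: {m!r}")
        mets.append(
            Metabolite(
                id=m["id"],
                compartment=str(m.get("compartment", "c")),
                name=m.get("name", ""),
            )
        )
    rxns = []
    objective_id = None
    for r in doc["reactions"]:
        if "id" not in r:
            raise FormatError(f"{path}: reaction entry without id: {r!r}")
        try:
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                enzyme_associated=bool(r.get("gene_reaction_rule", "").strip()),
                name=r.get("name", ""),
            )
        except ModelValidationError as exc:
            raise ModelValidationError(f"{path}: {exc}") from exc
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            objective_id = r["id"]
        rxns.append(rxn)
    if objective_id is None:
        raise ModelValidationError(
            f"{path}: no reaction carries a nonzero objective_coefficient"
        )
    return MetabolicModel(
        metabolites=mets, reactions=rxns, objective_id=objective_id,
        id=doc.get("id", path.stem),
    )


def _read_sbml_model(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises heterogeneous parse errors
        raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
    mets = [
        Metabolite(id=m.id, compartment=m.compartment or "c", name=m.name or "")
        for m in cmodel.metabolites
    ]
    objective_id = None
    for rxn, coeff in cmodel.objective.expression.as_coefficients_dict().items():
        rid = getattr(rxn, "name", None)
        if rid and float(coeff) != 0.0:
            objective_id = str(rid).removesuffix("_reverse").rsplit("_reverse_", 1)[0]
    # cobra's objective expression uses forward/reverse solver variables;
    # fall back to scanning objective coefficients on reactions.
    for r in cmodel.reactions:
        if r.objective_coefficient:
            objective_id = r.id
    rxns = []
    for r in cmodel.reactions:
        try:
            rxns.append(
                Reaction(
                    id=r.id,
                    stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                    lower_bound=float(r.lower_bound),
                    upper_bound=float(r.upper_bound),
                    enzyme_associated=bool(r.gene_reaction_rule.strip()),
                    name=r.name or "",
                )
            )
        except ModelValidationError as exc:
            raise ModelValidationError(f"{path}: {exc}") from exc
    if objective_id is None:
        raise ModelValidationError(f"{path}: model declares no objective reaction")
    return MetabolicModel(
        metabolites=mets, reactions=rxns, objective_id=objective_id, id=cmodel.id
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the BiGG-style JSON dialect (exact round-trip)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": "G_%s" % r.id if r.enzyme_associated else "",
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [],
        "compartments": sorted({m.compartment for m in model.metabolites}),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# flux reports
# ---------------------------------------------------------------------------


def write_flux_report(solutions: Iterable, path: str | Path) -> None:
    """Write a sweep of solutions as a TSV matrix (rows = reactions).

    Columns come in ascending-fraction order, one raw (``flux_f<frac>``) and
    one normalized-by-objective (``rel_f<frac>``) column per solution.
    """
    solutions = sorted(solutions, key=lambda s: s.fraction)
    if not solutions:
        logger.warning("write_flux_report: empty solution list, writing header only")
        pd.DataFrame(columns=["reaction_id"]).to_csv(path, sep="\t", index=False)
        return
    rxn_ids = sorted(solutions[0].net_fluxes)
    data: dict[str, list[float]] = {"reaction_id": rxn_ids}
    for sol in solutions:
        tag = f"{sol.fraction:g}"
        data[f"flux_f{tag}"] = [sol.net_fluxes.get(r, 0.0) for r in rxn_ids]
        obj = sol.objective_value
        data[f"rel_f{tag}"] = [
            (sol.net_fluxes.get(r, 0.0) / obj if obj else math.nan) for r in rxn_ids
        ]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_flux_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="reaction_id")
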
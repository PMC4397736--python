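# Methods

## The two-step protein-cost solve

Ordinary flux balance analysis (FBA) picks, from the steady-state flux
polytope {v : S·v = 0, lb ≤ v ≤ ub}, a vector maximizing one objective
reaction — usually biomass production. `corso` instead treats the biomass
level as a *condition*: step one computes the FBA optimum Z\*, step two
pins the objective flux to f·Z\* for a chosen fraction f ∈ (0, 1] by an
equality constraint and minimizes an estimated protein cost over the
remaining freedom. Sweeping f (default 0.50–1.00 in steps of 0.01) traces
pathway usage across the near-optimal solution space.

The per-reaction cost of carrying flux J is

    J · MW · exp(α · ΔrG'° / RT),      α = 0.02·RT mol/kcal,

so the thermodynamic factor reduces to exp(0.02 · ΔrG'°[kcal/mol]) and is
temperature-independent. MW (kDa) stands in for the resource cost of
expressing enough enzyme to sustain the flux; the exponential penalizes
running a reversible reaction in its thermodynamically unfavorable
direction (the backward direction of a reaction gets the reciprocal
factor). The penalty is applied only to reversible reactions:
irreversibility is taken as evidence the direction is already favorable.
The α scaling keeps the two terms comparable; without it the exponential
dominates and directionality would be dictated by ΔrG'° alone. The model
deliberately ignores turnover numbers and substrate affinities — kcat
values are scarce and strongly condition-dependent — so costs are
comparable only in a relative sense.

Four interchangeable cost functions are supported: `mw` (molecular weight
only), `thermo` (penalty only), `combined` (their product, the default)
and `uniform` (cost 1 per unit flux through every enzyme-associated
direction, which reduces the second step to a parsimonious-FBA-style
minimization of total enzymatic flux — a property the test suite checks
against an independent min-Σ|v| LP).

### Embedding the cost in the stoichiometry

Because cost is linear in flux, it is compiled into the network rather
than into the LP objective: every enzyme-associated reversible reaction
is split into irreversible forward/backward halves (`<id>__f`, `<id>__b`,
bounds [0, ub] and [0, −lb]); each enzyme-associated direction produces a
pseudo-metabolite `protein_cost__x` (own compartment, so SBML round-trips
stay interpretable) with its direction's cost coefficient; a single sink
`COST_SINK` consumes it. At steady state the sink flux *is* the total
protein cost, so step two minimizes one variable. Reactions without an
associated enzyme cost zero and are left unsplit; the cost-table `enzyme`
flag overrides the model's gene-association flag, and reactions absent
from the table are treated as non-enzymatic.

Simultaneous forward+backward flux on a split pair only adds cost, so
cost-minimal solutions carry no futile split cycles — asserted on solver
output.

### Numerical choices

* LPs are solved with scipy's HiGHS backend (dual feasibility tolerance
  well below the 1e-6 conservation tolerance asserted on every solution).
* The objective is fixed by *equality* at f·Z\*; a `"at_least"` mode
  relaxes it to a lower bound, but for cost minimization the equality
  binds on any sensible model.
* Alternate cost-minimal optima are disambiguated by a second LP that
  pins the cost at its minimum (slack 1e-9) and minimizes the summed
  split-direction fluxes; outputs are thereby reproducible across runs
  and platforms.
* Fluxes with |v| < 1e-9 are snapped to 0.
* Missing ΔrG'° values are treated as 0 (penalty factor 1): no estimate,
  no penalty.
* Missing molecular weights are imputed with the median of the known
  enzyme MWs (even count: mean of the two central values).
* "Arbitrarily large" bounds are encoded as ±1000, the common COBRA
  convention; units ride along opaquely (mmol·gDW⁻¹·h⁻¹ customary).

## Fundamental pathways

Extreme-pathway and elementary-mode decompositions explode on
genome-scale networks, largely because every pathway must balance
ubiquitous currency metabolites (ATP/ADP, NAD(H), protons, water,
phosphate, …) and many small loops can do that balancing, multiplying
pathways that share one backbone. The decomposition here:

1. **Currency removal.** A configurable list of currency metabolites
   (default: atp, adp, amp, pi, ppi, nad, nadh, nadp, nadph, h, h2o,
   coa, co2, matched across compartments by base name) is deleted from
   every reaction in every compartment. Reactions emptied by the removal
   are dropped. Three cautions are checked: removal must be complete
   (guaranteed by construction); no retained reaction should become a
   pure source or sink (violations are *warnings*, not errors — the
   decomposition remains usable, with caveats); dropped reactions must
   not contain surviving metabolites (guaranteed: only emptied reactions
   are dropped).
2. **Exact enumeration.** Reversible reactions (exchanges included) are
   split into irreversible columns and the extreme rays of
   {v ≥ 0 : S_reduced·v = 0} are enumerated by double description with
   stdlib `fractions.Fraction` arithmetic — balances hold *exactly*, not
   to a tolerance. Constraint rows are inserted in order of increasing
   support (the classic heuristic) and after each insertion the candidate
   set is pruned to proportional-unique, support-minimal rays; for flux
   cones the support-minimal nonzero solutions are exactly the extreme
   rays, which makes the prune sound. Forward∘backward two-cycles are
   discarded; each ray is scaled to smallest integers. Enumeration is
   exponential in the worst case, so networks above 80 split columns are
   refused unless the guard is raised.
3. **Imbalance.** Each ray, mapped back to net fluxes on the original
   reactions, generally does *not* balance the removed metabolites:
   S_original·v is its imbalance (e.g. +2 ATP per glucose for glycolysis
   to lactate). Retained metabolites stay balanced by construction. The
   removed balancing reactions can be added back by solving
   S_removed·x = −imbalance exactly (Gauss–Jordan over rationals, free
   variables at 0), recovering a fully balanced full-model flux vector.
4. **ATP potential and cost.** A pathway's ATP potential is its direct
   ATP imbalance plus each surplus energy carrier (default list: nadh,
   nadph, q8h2, fadh2) converted at the cheapest rate the full model
   achieves: with all exchange uptakes closed, a pseudo-reaction
   regenerating the reduced carrier from its oxidized partner is fixed at
   flux 1, the ATP drain (`ATPM`-style hydrolysis) is maximized, and the
   protein cost is minimized at that yield. Pathways are normalized per
   mmol glucose when they take glucose up. Carrier *consumption*
   subtracts yield·|imbalance| symmetrically — a convention, flagged in
   reports, since only surplus crediting is obviously principled.
   Total cost = pathway enzyme cost + conversion cost of surplus
   carriers; cost per ATP is their ratio (+∞ for non-positive potential).
5. **Classification.** On the (ATP per glucose, cost per ATP) plane the
   non-dominated pathways are *optimal* (OP). A dominated pathway is
   *near-optimal* (NOP) unless some OP beats it by more than a 10%
   relative margin on both axes simultaneously (margin configurable).
   Internal cycles touching no exchange reaction (type III loops) are
   flagged and never scored.

## What the toy fixtures emulate — and what they do not

* **mini-glycolysis** — textbook glycolysis stoichiometry from PTS uptake
  to D-lactate secretion (1 glucose → 2 lactate, net +2 ATP) plus the
  balancing set: ATP maintenance hydrolysis (`ATPM`, also the energy
  objective), an ATP synthase and a proton leak. The leak runs
  down-gradient only and protons are secretion-only at the boundary;
  otherwise the synthase would be a perpetual ATP source (a real failure
  mode of careless toy networks). Exhibits loop-induced pathway
  multiplicity collapsing to a single fundamental pathway.
* **overflow** — two parallel glucose→biomass routes (yields 2 and 1,
  per-flux costs 10 and 3 by default): the cost-minimal solution uses
  only the cheap low-yield route up to the analytically derivable switch
  fraction f\* = yield_lo/yield_hi = 0.5, then mixes, and is forced onto
  the high-yield route at f = 1 by the glucose budget — the
  cost-versus-yield tradeoff behind overflow metabolism, in its smallest
  expressible form.
* **toy ETC** — NADH pumps 8 protons, the synthase charges 4 per ATP and
  returns 3, so one NADH yields exactly 2 ATP; used to pin down carrier
  conversion yields and costs against a hand-solved LP.
* **loop** — a production chain plus an A→B→C→A internal cycle: the type
  III detector must flag it and the solver must leave it unused.

These fixtures have exact, hand-derivable answers; that is their point
and their limitation. They contain no alternate cofactor pools, no
compartmental proton-motive coupling beyond one synthase, no biomass
composition, and none of the degeneracy of genome-scale reconstructions.
Passing tests therefore demonstrate correctness of the *algorithms*
(LP equivalence to vertex enumeration, enumeration equivalence to
exhaustive support search, exact balances), not predictive accuracy on
real organisms. Randomized toys (seeded, ≤ 8 reactions for the LP oracle,
≤ 12 split columns for the cone oracle, 20 instances each) keep the
oracle comparisons honest at sizes where brute force is exhaustive; these
problem sizes were chosen so the full suite stays in the seconds range.

## Known limitations

* Costs omit kcat and substrate affinity by design; growth-rate
  prediction is out of scope (fractions are conditions, not predictions,
  and no mapping from dilution rate to f is attempted).
* Extreme-ray enumeration above the column guard is refused rather than
  attempted; genome-scale decomposition is not a target.
* The currency and carrier lists are conventions to be overridden per
  model; whether NADPH should be credited toward ATP potential is a
  modeling choice left to the carrier list.
* One MW per reaction: isozyme selection happens upstream, in whatever
  builds the cost table.
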
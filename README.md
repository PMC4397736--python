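# corso

Protein-cost-minimal flux distributions at sub-optimal growth, and
currency-reduced fundamental pathway analysis, for constraint-based
metabolic models.

## The problem

Flux balance analysis (FBA) predicts metabolic fluxes by maximizing a
biomass objective over the steady-state cone {v : S·v = 0, lb ≤ v ≤ ub}.
That works well for growth rates and gene essentiality, but internal
fluxes are poorly determined: the optimum is degenerate, and real cells —
*E. coli* included — often grow below their predicted maximum, where the
solution space is even larger. `corso` is for modelers who want to
*explore* that sub-optimal space rather than collapse it with extra
constraints at the optimum.

Two ideas, implemented as a small Python library with a CLI:

**1. Two-step cost-minimal FBA.** Fix the objective at a fraction
f ∈ (0, 1] of its FBA maximum, then minimize an enzyme protein cost

&nbsp;&nbsp;&nbsp;&nbsp;Σᵢ Jᵢ · MWᵢ · exp(α·ΔᵣG′°ᵢ / RT),&nbsp;&nbsp;&nbsp;α = 0.02·RT mol/kcal,

where Jᵢ is the flux, MWᵢ the enzyme molecular weight (kDa) and ΔᵣG′°ᵢ
the standard Gibbs free energy of reaction (kcal/mol); the thermodynamic
factor reduces to exp(0.02·ΔᵣG′°) and applies only to reversible
reactions, reciprocal per direction. The cost is embedded in the
stoichiometry: enzyme reactions are split into irreversible halves, each
producing a `protein_cost__x` pseudo-metabolite consumed by a single
`COST_SINK`, so the sink flux *is* the total cost and the second step
minimizes one LP variable. Sweeping f from 0.5 to 1.0 shows how pathway
usage (e.g. respiration versus overflow routes) shifts across the
near-optimal space.

**2. Fundamental pathways.** Extreme-pathway decompositions explode
because currency metabolites (ATP/ADP, NAD(H), H⁺, H₂O, Pi, …) must be
balanced and countless small loops can do it. Deleting those metabolites
from the network and enumerating the extreme rays of the reduced cone —
exactly, in rational arithmetic — yields far fewer *fundamental
pathways*, each annotated with the imbalance S_original·v it would cause
in the full model, an ATP production potential (crediting surplus NADH,
ubiquinol-8, … at their cheapest conversion yield), a protein cost per
ATP, and an optimal/near-optimal (OP/NOP) Pareto classification.

## Worked example

The bundled mini-glycolysis fixture encodes the textbook glucose→lactate
pathway plus the ATP/proton balancing loops that inflate plain
extreme-pathway counts:

```python
from corso import *
from corso.fixtures import make_glycolysis_fixture, GLYCOLYSIS_CURRENCY

model, costs = make_glycolysis_fixture()
aug = augment_model(model, build_cost_coefficients(model, costs, "combined"))

opt, _ = maximize_objective(aug)
sol = solve_corso(aug, fraction=1.0)
print(opt, round(sol.net_fluxes["EX_lac__D_e"], 6),
      round(sol.net_fluxes["EX_glc__D_e"], 6))

reduced = reduce_model(model, GLYCOLYSIS_CURRENCY)
(p,) = enumerate_pathways(reduced)
annotate_imbalance(p, model)
print(p.imbalance["atp_c"], p.net_flux["EX_lac__D_e"])
```

prints

```
15.0 20.0 -10.0
2 2
```

Line one: the energy objective (ATP maintenance flux) maxes out at 15 for
a glucose uptake of 10 — glycolysis nets 2 ATP per glucose and exporting
the surplus protons through the ATP-driven pump costs the other 5 — and
the cost-minimal solution at f = 1 secretes 20 lactate per 10 glucose,
the stoichiometric yield of 2. Line two: after removing ATP, ADP, Pi, H,
H₂O, NAD and NADH, the whole network collapses to a *single* fundamental
pathway whose full-model imbalance is +2 ATP per glucose and whose
lactate secretion is 2 per glucose — the worked example the decomposition
is built around. (Values are exact rationals, hence `2`, not `2.0`.)

The same workflows run from the shell:

```sh
corso fixtures --name glycolysis --out demo/
corso solve --model demo/model.json --costs demo/costs.tsv --fraction 0.85
corso sweep --model demo/model.json --costs demo/costs.tsv \
      --from 0.5 --to 1.0 --step 0.01 --normalize glc_g6p \
      --glc-g6p-id GLCpts --out sweep.tsv
corso pathways --model demo/model.json --costs demo/costs.tsv \
      --glc-exchange-id EX_glc__D_e --out pathways.tsv
corso compare --sweep sweep.tsv --exp exp_fluxes.tsv --out cmp.tsv
```

Inputs are BiGG-style JSON or SBML L3+FBC models, a tab-separated cost
table (`reaction_id  mw_kda  dG0_kcal_mol  enzyme`; missing MWs are
median-imputed, non-enzyme rows cost zero) and an optional medium file
(`exchange_id  uptake_bound  secretion_allowed`).

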
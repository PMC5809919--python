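# fruits

**F**inds **R**eactions **U**sable **i**n **T**apping **S**ide-products —
a constraint-based screen that turns anabolic side-products into
growth-coupled products.

## The problem

Engineered production strains are genetically unstable: making product
competes with making biomass, so non-producing mutants grow faster and
take over. One escape is *growth-coupled production* — rewiring the
network so that any biomass formation stoichiometrically forces product
secretion, putting Darwinian selection on the producer's side.

Many anabolic reactions co-produce small metabolites (acetate from
*O*-acetyl-L-homoserine conversion, 5′-deoxyadenosine from radical-SAM
chemistry, ...) that cells normally re-assimilate. If the re-utilization
pathway is deleted, the side product must accumulate in strict
proportion to flux through the anabolic pathway — and hence to growth.
This package screens a genome-scale metabolic model (GSM) for every
metabolite that can be coupled this way, and reports the gene knockouts
plus the predicted growth and secretion rates.

## The method

Given a GSM with flux bounds, gene–protein–reaction (GPR) rules and a
biomass objective, the screen:

1. computes a parsimonious flux distribution (pFBA) for the constrained
   wild type;
2. collects side-product candidates: metabolites co-produced (≥ 2
   products in the flux direction) by flux-carrying, non-exchange,
   non-transport reactions, excluding direct biomass substrates;
3. trims candidates to carbon-containing non-cofactors;
4. per candidate, ensures an export route (existing drain, one-hop
   transporter + exchange, or an inserted sink `SK_<met>`), then solves
   a **gene-level OptKnock**: the bilevel program

   max (over ≤ K gene deletions) v_target
   s.t. v solves { max v_biomass : S·v = 0, lb·a ≤ v ≤ ub·a },

   collapsed to a single-level MILP via LP strong duality, with binary
   gene variables driving per-reaction activity `a` through an exact
   linearization of the boolean GPRs;
5. certifies obligatory coupling by flux variability analysis (FVA) at
   100% of the deletion model's growth optimum: the candidate is
   reported only if the *minimum* secretion flux is positive. The yield
   on biomass is Y_p/x = v_min/µ (mmol gDW⁻¹), also reported per carbon
   (C-mol yield).

A brute-force enumerator over gene subsets provides an independent
oracle, and a generator of toy networks with closed-form expected
output makes the whole screen testable without any model download.
Companion modules cover reaction-direction thermodynamics from
concentration ratios (ΔG = ΔG°′ + RT·ln10·Σ log₁₀ ratios) and
growth/yield estimation from turbidostat and batch cultivation traces.

## Worked example

```python
from fruits import ToySpec, make_coupled_toy, run_fruits, FruitsConfig

spec = ToySpec()                      # one side product, stoich 0.2/precursor
model, expected = make_coupled_toy(spec)
report = run_fruits(model, FruitsConfig(max_deletions=1))
entry = report.entries[0]
print(f"wild-type growth {report.wild_type_growth:.3f} h^-1")
print(f"{entry.metabolite_id}: delete {sorted(entry.design.deleted_genes)}, "
      f"growth {entry.growth_rate:.3f}, yield {entry.yield_on_biomass:.3f} "
      f"mmol/gDW, strict={entry.strict}")
```

prints

```
wild-type growth 12.000 h^-1
sp1_c: delete ['g1a'], growth 10.000, yield 0.200 mmol/gDW, strict=True
```

Read: the wild type grows at 12 h⁻¹ (toy units) while recycling its side
product; deleting the single recycler gene `g1a` drops growth to 10 h⁻¹
and forces secretion of 0.2 mmol of side product per gDW of biomass —
exactly the constructed co-production stoichiometry — with FVA minimum
equal to maximum (`strict=True`), i.e. secretion is pinned by growth.

The same screen runs on any SBML model from the shell:

```bash
fruits run --model model.xml --max-deletions 4 --min-growth-fraction 0.1 \
           --out report.tsv --audit audit.json
fruits candidates --model model.xml
fruits verify --model model.xml --genes sll0542,sll1299 --target ac_c
fruits thermo --dg0 11.6 --ratio adp_atp=0.5 --solve acp_ac
fruits cultivation simulate --seed 1 --out trace.csv
fruits cultivation fit --trace trace.csv
```

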
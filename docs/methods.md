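# Methods

## Model and scope

The package operates on genome-scale metabolic models under the
standard constraint-based assumptions: steady state (S·v = 0), flux
bounds, and growth as the cellular objective. Reaction availability is
a monotone boolean function of gene presence (AND = complex subunits,
OR = isozymes); a gene deletion zeroes the bounds of every reaction
whose GPR evaluates false, and never touches reactions without a GPR.
Models are held as `cobra.Model` objects; SBML I/O, FBA, parsimonious
FBA and FVA go through cobrapy with GLPK as the LP/MILP backend. The
screen itself — candidate identification, the gene-level OptKnock
MILP, the coupling certificate and the enumeration oracle — is
implemented here.

All tolerances trace to three constants: LP feasibility/optimality
1e-6, flux values below 1e-9 reported as zero, and a production
threshold of 1e-6 below which a target flux counts as "no secretion".
Strictness of coupling requires |FVA max − FVA min| < 1e-6. Bilevel
solutions are re-verified against plain FBA/FVA within 1e-5.

## Candidate identification

The screen needs the products of anabolism that are *co-produced*
rather than consumed onward as pathway intermediates. The default
heuristic works on a parsimonious reference optimum (pFBA resolves
alternate optima, making the reference reproducible): a reaction is
"anabolic" if it carries flux and is neither an exchange, nor a
transport step (spans ≥ 2 compartments), nor the biomass reaction; its
products in the flux direction are candidates whenever the reaction
makes two or more of them and the product is not itself a biomass
substrate.

A natural-looking alternative — calling a product "main" whenever some
flux-carrying reaction consumes it — is deliberately not used: at
steady state a recycled side product is *always* consumed by its
re-utilization pathway, so that rule removes precisely the metabolites
the screen exists to find. The permissive rule lets some true pathway
intermediates through; they are harmless, because the OptKnock stage
finds no deletion set that forces their secretion and the FVA
certificate rejects them. A subsystem-annotation variant
(`candidate_method="subsystem"`) selects anabolic reactions by
biosynthesis keywords instead, for models with reliable subsystem
curation.

Trimming keeps candidates with ≥ 1 carbon atom (by Hill-formula
parsing; metabolites without a formula are excluded with a warning)
that are not on the cofactor list. The shipped list covers the usual
energy/redox carriers (ATP/ADP/AMP, NAD(P)(H), FAD(H₂), nucleotide
phosphates, quinones, CoA, plus H₂O/H⁺/CO₂/Pi/PPi/O₂). Free CoA is
excluded as a carrier; acyl thioesters such as acetyl-CoA are not
listed. The file is editable and replaceable per run.

## Gene-level OptKnock

The bilevel program (outer: choose ≤ K deletions to maximize target
secretion; inner: the cell maximizes biomass) is collapsed to one MILP
by strong duality: primal feasibility, dual feasibility of the inner
LP, and the equality "primal objective = dual objective" hold
simultaneously, which forces any feasible point to be inner-optimal.
Binary presence variables y_g feed per-reaction activity variables
through exact AND (t ≤ cᵢ, t ≥ Σcᵢ − (n−1)) and OR (t ≥ cᵢ, t ≤ Σcᵢ)
encodings; activity scales the flux bounds (lb·a ≤ v ≤ ub·a) and the
corresponding dual bound terms, whose bilinear products are linearized
with big-M = 1000, matching the customary bound magnitude in GSMs
(models with larger bespoke bounds need a rescaled M). Dual variables
are capped at the same M. Because big-M linearizations can admit
spurious solutions, every returned design is re-simulated by FBA and
FVA on the deletion model, and those ground-truth numbers are what the
design carries.

OptKnock's objective is the *optimistic* secretion — the best flux
among inner-optimal states — which does not by itself prove obligatory
coupling. Each design therefore also records the *guaranteed* flux
(FVA minimum at 100% of the deletion model's optimum), and the screen
accepts a candidate only on a positive guaranteed flux.

After the first solve, the incumbent deletion set is minimalized by
testing each gene's removal against the FBA/FVA optimum (the MILP has
no incentive to keep deletion sets small), and co-optimal alternates
are enumerated — bounded to 10 — by adding no-good cuts
(Σ_{g∈D} y_g ≥ 1) and re-solving under the unchanged objective.
Enumerating with a changed objective under a pinned target flux proved
numerically fragile with GLPK's branch-and-bound (the strong-duality
equality pins the target to a point, and a 1e-6 pin slack is below
what the MIP solver tolerates), so the pool keeps the original
objective throughout. Ties among designs break toward fewer deletions,
then the lexicographically smallest gene set; guaranteed fluxes are
rounded at 1e-9 in the comparison so solver noise cannot override the
tie-break.

A growth floor — `min_growth_fraction` × wild-type optimum, default
0.1 — excludes non-growing designs while remaining permissive;
published growth-coupled designs typically grow at well above half the
wild-type rate.

The brute-force oracle enumerates every gene subset of size ≤ K
(guarded at 20,000 subsets), scores each by FBA growth plus the FVA
minimum of the target at that optimum, and keeps obligatory producers.
It shares no code path with the MILP beyond the FBA/FVA primitives and
is the reference in the equivalence tests.

## Export routes and model edits

A candidate can only be predicted to accumulate if it can cross the
system boundary. The screen uses, in order of preference: an existing
drain on the metabolite itself; the exchange reaction of a one-hop
transport partner in another compartment; or a newly inserted
irreversible sink `SK_<met>` with bounds [0, 1000]. Multi-hop export
chains (e.g. cytosol → periplasm → external) are not searched; such
metabolites simply receive a sink. Sink insertion is idempotent and,
at zero sink flux, provably leaves the pre-existing flux space
unchanged. Directionality edits (`set_reaction_irreversible`) clamp
the bound opposing the stated direction and leave the other bound
untouched, e.g. for revising a reversible acetate kinase after a
thermodynamic analysis.

## Thermodynamics from concentration ratios

For reactions whose quotient factors into unimolecular concentration
ratios, ΔG = ΔG°′ + RT·ln10·Σ log₁₀(ratio); each ratio decade
contributes RT·ln10 ≈ 5.8 kJ mol⁻¹ at the default 303.15 K (30 °C
cultivation). ΔG°′ is always a user input — standard-condition
energies belong to dedicated calculators and are not bundled or
fabricated here. `min_substrate_excess` inverts the relation: fixing
all but one ratio, it solves ΔG = 0 for the free product:substrate
ratio and reports the required substrate fold-excess; values of ~10²
are the package's quantitative basis for declaring a direction
infeasible in vivo. No pH, ionic-strength or activity corrections are
applied — these are the user's responsibility when choosing ΔG°′.

## Cultivation analytics

Growth rate is estimated per growth–dilution cycle as the OLS slope of
ln(OD) against time, aggregated as the mean across cycles; cycles come
from explicit dilution stamps or are detected as relative OD drops
exceeding half the nominal dilution fraction (robust to ~1% noise at
5-min sampling). Cycles with fewer than 4 valid points are discarded.
A perfectly flat cycle has slope 0 with R² = 1 by the zero-residual
convention.

Yield on biomass Y_p/x is the OLS slope of product concentration (mM)
against dry-weight concentration over a stated time window, with OD
converted by an explicit coefficient (default 148 mg L⁻¹ per OD unit —
an instrument-specific constant, never hard-coded into formulas).
Units are mmol gDW⁻¹ throughout (numerically identical to mM gDW⁻¹ at
1 L reference volume; the mmol form is used consistently). The
biomass-specific productivity is computed as q_p = µ × Y over a window
rather than by differentiating sparse product samples; at steady state
the two coincide, and the windowed form is far less noise-sensitive.

The turbidostat simulator grows the true state exponentially between
instantaneous fractional dilutions triggered at a sampling instant
when OD exceeds the threshold (default: 8% dilution at OD > 0.35,
5-min sampling), accumulates product as yield × new biomass, dilutes
both identically, and adds multiplicative log-normal observation noise
per channel. It emulates observation noise only — no growth-rate
fluctuations, sensor drift, fouling, adaptation or mutation — so
parameter-recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to real instrument pathology.

Recovery checks run at the study's working point: µ = 0.048 h⁻¹ and
Y = 0.195 mmol gDW⁻¹, month-long (720 h) turbidostat traces for µ,
120 h batch traces with a 65–120 h window for Y, twelve cultures
spanning µ = 0.02–0.09 h⁻¹ for the q_p–µ regression, 20 fixed seeds.
The long-run stability check regresses per-cycle estimates of µ and
q_p on time and expects no trend (p > 0.05 under the simulator's
null); being a significance test it carries a nominal 5% false-alarm
rate and runs derandomized.

## Synthetic benchmark networks

Each toy network contains the screened motif in miniature: substrate
uptake (bound u), per-precursor synthesis reactions co-producing side
product i at stoichiometry sᵢ, a biomass reaction consuming each
precursor with coefficient 1, and a gene-gated recycler per side
product (single gene, OR isozyme pair, or AND complex). Yields are
closed-form: with full recycling the synthesis flux per unit growth is
1/(1+sᵢ), so wild-type growth is u/Σⱼ 1/(1+sⱼ); cutting recycler i
forces secretion sᵢ·µ with µ = u/(1 + Σ_{j≠i} 1/(1+sⱼ)), and the yield
on biomass is exactly sᵢ. Coupling is strict by construction (the sink
or exchange is the only outlet once the recycler is gone). Fuzzed
instances stay within 8 genes and 15 reactions so the enumeration
oracle is exact and fast; half give side products an explicit
transporter + exchange, half leave them without any outlet, exercising
both export-route branches. These networks share no mechanism with
real GSM pathologies (no alternate optima families, no nested
redundancy across pathways, no maintenance fluxes), so passing them
validates the machinery, not model-specific conclusions.

## Known limitations

- Candidate counts on real models depend strongly on the candidate
  heuristic; the two shipped variants bracket reasonable choices but
  neither is guaranteed to reproduce a particular published candidate
  list.
- Big-M duality caps can, in principle, truncate the dual space for
  models with unusual bound magnitudes; the FBA/FVA re-verification
  catches (and logs) any resulting mismatch.
- GLPK's MIP performance limits the MILP to modest gene counts per
  candidate model version; genome-scale screens run, but at
  minutes-to-hours for a full K=4 pass.
- Export-route resolution is single-hop; metabolites behind multi-hop
  transport chains receive an intracellular sink instead, which can
  overstate secretion feasibility for compartmentalized products.
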
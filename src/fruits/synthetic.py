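"""Generator of small metabolic models with known growth-coupling structure.

Each toy model mimics, in miniature, the network motif the screen
targets: anabolic precursor-synthesis reactions that co-produce a side
product in fixed stoichiometry, a biomass reaction consuming the
precursors, and gene-gated "recycler" reactions that re-assimilate each
side product into its precursor pool.  Deleting a side product's
recycler(s) forces its secretion in strict proportion to growth, so the
expected screen output — deletion set, growth rate, guaranteed flux,
yield — is available in closed form:

with uptake bound ``u``, per-precursor biomass coefficient 1 and side
product stoichiometry ``s_i`` per precursor ``i``, full recycling gives
precursor-synthesis flux ``mu / (1 + s_i)`` per unit growth, hence

    wild-type growth      mu_wt = u / sum_j 1/(1+s_j)
    growth after cutting
    recycler i            mu_i  = u / (1 + sum_{j!=i} 1/(1+s_j))
    guaranteed flux       s_i * mu_i   (strictly coupled: FVA min = max)
    yield on biomass      s_i          (mmol per gDW)

Half of the fuzzed cases give each side product an explicit transporter
plus exchange; the other half leave it without any outlet so the screen
must insert a sink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from cobra import Metabolite, Model, Reaction

GPR_PATTERNS = ("single", "or", "and")


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one generated toy model."""

    n_side_products: int = 1
    #: per side product: "single" (one gene), "or" (isozyme pair —
    #: coupling needs two deletions), "and" (complex — one of two
    #: subunit genes suffices)
    recycler_redundancy: tuple[str, ...] = ("single",)
    #: mol side product co-produced per mol precursor synthesized
    side_product_stoichiometry: tuple[float, ...] = (0.2,)
    #: carbon atoms per side product molecule
    carbon_counts: tuple[int, ...] = (2,)
    #: whether each side product has a transporter + exchange already
    export_route: tuple[bool, ...] = (False,)
    #: substrate uptake bound, mmol gDW^-1 h^-1
    uptake_bound: float = 10.0
    seed: int = 0

    def __post_init__(self):
        n = self.n_side_products
        for name in ("recycler_redundancy", "side_product_stoichiometry",
                     "carbon_counts", "export_route"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length {n}")
        if any(p not in GPR_PATTERNS for p in self.recycler_redundancy):
            raise ValueError(f"patterns must be among {GPR_PATTERNS}")
        if any(c < 1 for c in self.carbon_counts):
            raise ValueError("carbon counts must be >= 1")
        if any(s <= 0 for s in self.side_product_stoichiometry):
            raise ValueError("stoichiometries must be positive")
        if self.uptake_bound <= 0:
            raise ValueError("uptake bound must be positive")


@dataclass(frozen=True)
class ExpectedCoupling:
    """Closed-form screen outcome for one side product."""

    metabolite_id: str
    target_reaction_id: str
    deleted_genes: frozenset[str]
    deletions_required: int
    growth_rate: float
    min_flux: float          # equals max_flux — coupling is strict
    yield_on_biomass: float
    cmol_yield: float
    carbons: int


def make_coupled_toy(spec: ToySpec) -> tuple[Model, list[ExpectedCoupling]]:
    """Build the toy model and its closed-form expected screen results.

    Deterministic: the same spec always yields an identical model.
    """
    n = spec.n_side_products
    model = Model(f"toy_{n}sp")
    model.compartments = {"c": "cytosol", "e": "extracellular"}

    sub_e = Metabolite("sub_e", name="substrate (external)",
                       compartment="e", formula="C6H12O6")
    sub_c = Metabolite("sub_c", name="substrate", compartment="c",
                       formula="C6H12O6")
    mets = [sub_e, sub_c]
    reactions = []

    ex_sub = Reaction("EX_sub_e", lower_bound=-spec.uptake_bound,
                      upper_bound=1000.0)
    ex_sub.add_metabolites({sub_e: -1})
    t_sub = Reaction("T_sub", lower_bound=0.0, upper_bound=1000.0)
    t_sub.add_metabolites({sub_e: -1, sub_c: 1})
    reactions += [ex_sub, t_sub]

    biomass = Reaction("R_BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    expected: list[ExpectedCoupling] = []

    inv_sum = sum(1.0 / (1.0 + s) for s in spec.side_product_stoichiometry)
    for i in range(1, n + 1):
        s = spec.side_product_stoichiometry[i - 1]
        carbons = spec.carbon_counts[i - 1]
        prec = Metabolite(f"prec{i}_c", name=f"precursor {i}",
                          compartment="c", formula=f"C3H{4 + i}O3")
        sp = Metabolite(f"sp{i}_c", name=f"side product {i}",
                        compartment="c",
                        formula=f"C{carbons}H{2 * carbons}O2")
        mets += [prec, sp]

        syn = Reaction(f"SYN{i}", lower_bound=0.0, upper_bound=1000.0)
        syn.add_metabolites({sub_c: -1, prec: 1, sp: s})
        rec = Reaction(f"REC{i}", lower_bound=0.0, upper_bound=1000.0)
        rec.add_metabolites({sp: -1, prec: 1})
        reactions += [syn, rec]
        biomass.add_metabolites({prec: -1})

        pattern = spec.recycler_redundancy[i - 1]
        ga, gb = f"g{i}a", f"g{i}b"
        if pattern == "single":
            rule, deleted, needed = ga, frozenset({ga}), 1
        elif pattern == "or":
            rule, deleted, needed = f"{ga} or {gb}", frozenset({ga, gb}), 2
        else:  # and — either subunit deletion disables; tie-break picks ga
            rule, deleted, needed = f"{ga} and {gb}", frozenset({ga}), 1

        if spec.export_route[i - 1]:
            sp_e = Metabolite(f"sp{i}_e", name=f"side product {i} (external)",
                              compartment="e",
                              formula=f"C{carbons}H{2 * carbons}O2")
            mets.append(sp_e)
            t_sp = Reaction(f"T_sp{i}", lower_bound=0.0, upper_bound=1000.0)
            t_sp.add_metabolites({sp: -1, sp_e: 1})
            ex_sp = Reaction(f"EX_sp{i}_e", lower_bound=0.0,
                             upper_bound=1000.0)
            ex_sp.add_metabolites({sp_e: -1})
            reactions += [t_sp, ex_sp]
            target = ex_sp.id
        else:
            target = f"SK_sp{i}_c"  # inserted by the screen

        growth = spec.uptake_bound / (1.0 + inv_sum - 1.0 / (1.0 + s))
        expected.append(
            ExpectedCoupling(
                metabolite_id=sp.id,
                target_reaction_id=target,
                deleted_genes=deleted,
                deletions_required=needed,
                growth_rate=growth,
                min_flux=s * growth,
                yield_on_biomass=s,
                cmol_yield=s * carbons,
                carbons=carbons,
            )
        )
        rec.gene_reaction_rule = rule

    reactions.append(biomass)
    model.add_metabolites(mets)
    model.add_reactions(reactions)
    model.objective = "R_BIOMASS"
    return model, expected


def wild_type_growth(spec: ToySpec) -> float:
    """Closed-form wild-type growth rate of a toy model."""
    inv_sum = sum(1.0 / (1.0 + s) for s in spec.side_product_stoichiometry)
    return spec.uptake_bound / inv_sum


def fuzz_models(
    n: int, seed: int
) -> list[tuple[Model, list[ExpectedCoupling], ToySpec]]:
    """Randomized toy suite (≤ 8 genes, ≤ 15 reactions per model).

    Deterministic in (n, seed).  Export routes alternate between
    present and absent so sink insertion is exercised both ways.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    suite = []
    for k in range(n):
        n_sp = int(rng.integers(1, 4))
        patterns = tuple(
            str(rng.choice(GPR_PATTERNS)) for _ in range(n_sp)
        )
        stoich = tuple(
            round(float(rng.integers(1, 11)) * 0.05, 2) for _ in range(n_sp)
        )
        carbons = tuple(int(rng.integers(1, 7)) for _ in range(n_sp))
        exports = tuple(bool((k + j) % 2) for j in range(n_sp))
        spec = ToySpec(
            n_side_products=n_sp,
            recycler_redundancy=patterns,
            side_product_stoichiometry=stoich,
            carbon_counts=carbons,
            export_route=exports,
            uptake_bound=float(rng.choice([5.0, 10.0])),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        model, expected = make_coupled_toy(spec)
        suite.append((model, expected, spec))
    return suite
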
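"""Gene-level OptKnock: deletion sets that maximize product secretion.

The bilevel program — an outer search over gene deletions maximizing
target flux while the inner cell maximizes biomass — is collapsed to a
single-level MILP by LP strong duality: the inner problem's primal and
dual feasibility plus a primal-objective = dual-objective equality force
every feasible point to be an inner optimum.  Gene deletions enter
through binary presence variables tied to per-reaction activity via an
exact linearization of the (monotone) boolean GPR rules; a disabled
reaction has both flux bounds scaled to zero.

Bilinear products between reaction activity and dual bound multipliers
are linearized with a big-M constant matching the model's bound
magnitude; every returned design is therefore re-verified by a plain
FBA/FVA on the deletion model, which guards against big-M artifacts.

A brute-force enumerator over gene subsets doubles as an independent
oracle for small instances.

OptKnock maximizes the *optimistic* target flux (the best secretion
among inner-optimal states); it does not by itself certify obligatory
coupling.  The *guaranteed* flux — the FVA minimum at optimal growth —
is attached to every design, and the screen's verdict rests on it.
"""

from __future__ import annotations

import ast
import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import cobra
import optlang
from cobra.util.solver import linear_reaction_coefficients

from fruits import cba_core

logger = logging.getLogger(__name__)

#: Designs with guaranteed (or, for the MILP, optimistic) target flux at
#: or below this are treated as "no production".
PRODUCTION_THRESHOLD = 1e-6

#: Agreement required between the bilevel solution and its FBA/FVA
#: re-verification before a design is trusted.
VERIFY_TOLERANCE = 1e-5

DEFAULT_BIG_M = 1000.0


@dataclass(frozen=True)
class DeletionDesign:
    """A set of gene knockouts and its predicted phenotype.

    ``predicted_target_flux`` is the maximum secretion compatible with
    optimal growth (the OptKnock objective); ``guaranteed_min_flux`` is
    the FVA minimum under the same growth optimum — positive only when
    secretion is obligatory.
    """

    deleted_genes: frozenset[str]
    disabled_reactions: frozenset[str]
    target_reaction_id: str
    predicted_growth: float
    predicted_target_flux: float
    guaranteed_min_flux: float
    alternates: tuple[frozenset[str], ...] = field(default=())

    def sort_key(self):
        # flux rounded so solver noise cannot override the deliberate
        # tie-breaks (fewer deletions, then lexicographic gene ids)
        return (
            -round(self.guaranteed_min_flux, 9),
            len(self.deleted_genes),
            tuple(sorted(self.deleted_genes)),
        )


class _MilpBuilder:
    """Assemble the single-level strong-duality MILP for one model."""

    def __init__(self, model: cobra.Model, target_reaction: str, big_m: float):
        self.model = model
        self.target = target_reaction
        self.M = big_m
        objective = list(linear_reaction_coefficients(model))
        if len(objective) != 1:
            raise ValueError("model must have exactly one objective reaction")
        self.biomass = objective[0].id
        self.prob = optlang.Model(name="gene_optknock")
        self.v: dict[str, optlang.Variable] = {}
        self.y: dict[str, optlang.Variable] = {}
        self._aux = 0
        self._build()

    # -- GPR encoding ------------------------------------------------
    def _encode_gpr(self, node: ast.AST, constraints: list):
        """Return a [0,1] expression equal to the boolean node's value.

        AND: t <= c_i for all i and t >= sum(c) - (n-1);
        OR:  t >= c_i for all i and t <= sum(c).
        Exact for binary leaves (auxiliaries are forced integral).
        """
        if isinstance(node, ast.Name):
            return self.y[node.id]
        if not isinstance(node, ast.BoolOp):
            raise ValueError(f"unsupported GPR node {ast.dump(node)}")
        children = [self._encode_gpr(c, constraints) for c in node.values]
        self._aux += 1
        t = optlang.Variable(f"gpr_aux_{self._aux}", lb=0, ub=1)
        total = sum(children)
        if isinstance(node.op, ast.And):
            for c in children:
                constraints.append(optlang.Constraint(t - c, ub=0))
            constraints.append(
                optlang.Constraint(t - total, lb=-(len(children) - 1))
            )
        else:  # Or
            for c in children:
                constraints.append(optlang.Constraint(t - c, lb=0))
            constraints.append(optlang.Constraint(t - total, ub=0))
        return t

    # -- assembly ----------------------------------------------------
    def _build(self):
        model, M = self.model, self.M
        cons: list = []

        knockable = [
            r for r in model.reactions if r.gene_reaction_rule.strip()
        ]
        knockable_ids = {r.id for r in knockable}

        for gene in model.genes:
            self.y[gene.id] = optlang.Variable(f"y_{gene.id}", type="binary")

        # primal fluxes; knockable reactions must admit v = 0
        for rxn in model.reactions:
            lb, ub = rxn.lower_bound, rxn.upper_bound
            if rxn.id in knockable_ids:
                lb, ub = min(lb, 0.0), max(ub, 0.0)
            self.v[rxn.id] = optlang.Variable(f"v_{rxn.id}", lb=lb, ub=ub)

        # reaction activity from GPRs
        a: dict[str, optlang.Variable | int] = {}
        for rxn in knockable:
            a[rxn.id] = self._encode_gpr(rxn.gpr.body, cons)
            v = self.v[rxn.id]
            cons.append(
                optlang.Constraint(v - rxn.upper_bound * a[rxn.id], ub=0)
            )
            cons.append(
                optlang.Constraint(v - rxn.lower_bound * a[rxn.id], lb=0)
            )

        # steady-state mass balance
        for met in model.metabolites:
            if not met.reactions:
                continue
            expr = sum(
                rxn.metabolites[met] * self.v[rxn.id] for rxn in met.reactions
            )
            cons.append(optlang.Constraint(expr, lb=0, ub=0))

        # dual of the inner biomass-maximization LP
        lam = {
            met.id: optlang.Variable(f"lam_{met.id}", lb=None, ub=None)
            for met in model.metabolites
        }
        mu = {
            r.id: optlang.Variable(f"mu_{r.id}", lb=0, ub=M)
            for r in model.reactions
        }
        nu = {
            r.id: optlang.Variable(f"nu_{r.id}", lb=0, ub=M)
            for r in model.reactions
        }
        for rxn in model.reactions:
            c_j = 1.0 if rxn.id == self.biomass else 0.0
            expr = (
                sum(coef * lam[met.id] for met, coef in rxn.metabolites.items())
                + mu[rxn.id]
                - nu[rxn.id]
            )
            cons.append(optlang.Constraint(expr, lb=c_j, ub=c_j))

        # dual objective with activity-modulated bounds; bilinear terms
        # a_j * mu_j / a_j * nu_j linearized with big-M
        dual_terms = []
        for rxn in model.reactions:
            if rxn.id in knockable_ids:
                act = a[rxn.id]
                p = optlang.Variable(f"p_{rxn.id}", lb=0, ub=M)
                q = optlang.Variable(f"q_{rxn.id}", lb=0, ub=M)
                for z, d in ((p, mu[rxn.id]), (q, nu[rxn.id])):
                    cons.append(optlang.Constraint(z - d, ub=0))
                    cons.append(optlang.Constraint(z - M * act, ub=0))
                    cons.append(optlang.Constraint(z - d + M * (1 - act), lb=0))
                dual_terms.append(rxn.upper_bound * p - rxn.lower_bound * q)
            else:
                dual_terms.append(
                    rxn.upper_bound * mu[rxn.id] - rxn.lower_bound * nu[rxn.id]
                )

        # strong duality: inner primal objective equals inner dual objective
        cons.append(
            optlang.Constraint(self.v[self.biomass] - sum(dual_terms), lb=0, ub=0)
        )

        self.prob.add(cons)

    def constrain_deletions(self, max_deletions: int):
        self.prob.add(
            optlang.Constraint(
                sum(1 - y for y in self.y.values()), ub=max_deletions
            )
        )

    def constrain_growth(self, floor: float):
        if floor > 0:
            self.prob.add(
                optlang.Constraint(self.v[self.biomass], lb=floor)
            )

    def deleted_genes(self) -> frozenset[str]:
        return frozenset(g for g, y in self.y.items() if y.primal < 0.5)


def _verify_design(
    model: cobra.Model,
    genes: frozenset[str],
    target_reaction: str,
) -> tuple[float, float, float, frozenset[str]] | None:
    """FBA/FVA ground truth for a deletion set.

    Returns (growth, fva_min, fva_max, disabled_reactions) or None when
    the deletion model is infeasible.
    """
    with model:
        disabled = cba_core.knock_out(model, genes)
        fba_growth = model.slim_optimize(error_value=None)
        if fba_growth is None:
            return None
        ranges = cba_core.fva(model, [target_reaction], objective_fraction=1.0)
    rng = ranges[0]
    return float(fba_growth), rng.min_flux, rng.max_flux, frozenset(disabled)


def _minimalize(
    model: cobra.Model,
    deleted: frozenset[str],
    target_reaction: str,
    flux_floor: float,
    growth_floor: float,
) -> frozenset[str]:
    """Drop genes whose removal keeps the optimistic flux at the optimum.

    The MILP objective does not reward gene presence, so an incumbent
    may delete genes that contribute nothing; each gene is tested for
    removal against the FVA-maximum target flux at optimal growth.
    """
    for gene in sorted(deleted):
        candidate = deleted - {gene}
        verdict = _verify_design(model, candidate, target_reaction)
        if verdict is None:
            continue
        growth, _, fmax, _ = verdict
        if fmax >= flux_floor and growth >= growth_floor - 1e-9:
            deleted = candidate
    return deleted


def gene_optknock(
    model: cobra.Model,
    target_reaction: str,
    max_deletions: int,
    min_growth_fraction: float = 0.1,
    big_m: float = DEFAULT_BIG_M,
    pool_size: int = 10,
) -> DeletionDesign | None:
    """Find ≤ K gene deletions maximizing secretion through a target drain.

    Solves the strong-duality MILP (inner objective: biomass
    maximization), then enumerates up to ``pool_size`` co-optimal
    minimal deletion sets, re-verifies each by FBA + FVA on the deletion
    model, and returns the design with the highest *guaranteed* (FVA
    minimum) target flux; ties break toward fewer deletions, then the
    lexicographically smallest gene set.  Co-optimal alternates are kept
    on the returned design.

    Returns None when no deletion set pushes the optimistic target flux
    above 1e-6, or when the MILP is infeasible (e.g. the growth floor
    ``min_growth_fraction × wild-type optimum`` cannot be met).
    """
    if max_deletions < 0:
        raise ValueError("max_deletions must be >= 0")
    model.reactions.get_by_id(target_reaction)  # raises on unknown target

    wt = cba_core.fba(model)
    if not wt.optimal:
        raise ValueError("wild-type model is not solvable")
    growth_floor = min_growth_fraction * wt.objective_value

    builder = _MilpBuilder(model, target_reaction, big_m)
    builder.constrain_deletions(max_deletions)
    builder.constrain_growth(growth_floor)
    prob = builder.prob

    prob.objective = optlang.Objective(
        builder.v[target_reaction], direction="max"
    )
    status = prob.optimize()
    if status != "optimal":
        logger.info("OptKnock MILP %s for target %s", status, target_reaction)
        return None
    best_flux = prob.objective.value
    if best_flux <= PRODUCTION_THRESHOLD:
        return None

    # co-optimal pool under the unchanged objective: minimalize each
    # incumbent deletion set against FBA/FVA ground truth (the MILP is
    # free to delete irrelevant genes), then exclude it and every
    # superset with a no-good cut and re-solve
    tol = max(PRODUCTION_THRESHOLD, 1e-6 * abs(best_flux))
    pool: list[frozenset[str]] = []
    while len(pool) < pool_size:
        deleted = _minimalize(
            model, builder.deleted_genes(), target_reaction,
            best_flux - tol, growth_floor,
        )
        if deleted not in pool:
            pool.append(deleted)
        if not deleted:
            break
        prob.add(
            optlang.Constraint(
                sum(builder.y[g] for g in deleted), lb=1
            )
        )
        if prob.optimize() != "optimal":
            break
        if prob.objective.value < best_flux - tol:
            break

    designs: list[DeletionDesign] = []
    for deleted in pool:
        verdict = _verify_design(model, deleted, target_reaction)
        if verdict is None:
            continue
        growth, fmin, fmax, disabled = verdict
        if abs(fmax - best_flux) > max(VERIFY_TOLERANCE, 1e-5 * abs(best_flux)):
            logger.warning(
                "bilevel/FBA mismatch for %s (MILP %.6g vs FVA max %.6g); "
                "using the FBA/FVA values", sorted(deleted), best_flux, fmax,
            )
        designs.append(
            DeletionDesign(
                deleted_genes=deleted,
                disabled_reactions=disabled,
                target_reaction_id=target_reaction,
                predicted_growth=growth,
                predicted_target_flux=fmax,
                guaranteed_min_flux=fmin,
            )
        )
    if not designs:
        return None
    designs.sort(key=DeletionDesign.sort_key)
    best = designs[0]
    alternates = tuple(
        d.deleted_genes for d in designs[1:]
        if abs(d.guaranteed_min_flux - best.guaranteed_min_flux) <= VERIFY_TOLERANCE
        and len(d.deleted_genes) == len(best.deleted_genes)
    )
    if alternates:
        best = DeletionDesign(
            best.deleted_genes, best.disabled_reactions,
            best.target_reaction_id, best.predicted_growth,
            best.predicted_target_flux, best.guaranteed_min_flux,
            alternates=alternates,
        )
    return best


def brute_force_designs(
    model: cobra.Model,
    target_reaction: str,
    max_deletions: int,
    min_growth_fraction: float = 0.0,
    subset_guard: int = 20_000,
) -> list[DeletionDesign]:
    """Enumerate all gene subsets of size ≤ K; keep obligatory producers.

    Independent oracle for :func:`gene_optknock` on small instances: for
    every subset the deletion model is solved by plain FBA (growth) and
    the target's FVA minimum at the growth optimum is taken as the
    guaranteed flux.  Designs with guaranteed flux > 1e-6 are returned
    sorted by guaranteed flux (descending), then fewer deletions, then
    lexicographic gene ids.

    Raises when the subset count exceeds ``subset_guard`` — shrink the
    instance or K instead of waiting.
    """
    genes = sorted(g.id for g in model.genes)
    n_subsets = sum(comb(len(genes), k) for k in range(max_deletions + 1))
    if n_subsets > subset_guard:
        raise ValueError(
            f"{n_subsets} gene subsets exceed the guard of {subset_guard}; "
            "reduce max_deletions or the gene count"
        )
    wt = cba_core.fba(model)
    if not wt.optimal:
        raise ValueError("wild-type model is not solvable")
    growth_floor = min_growth_fraction * wt.objective_value

    designs: list[DeletionDesign] = []
    for k in range(max_deletions + 1):
        for subset in itertools.combinations(genes, k):
            deleted = frozenset(subset)
            verdict = _verify_design(model, deleted, target_reaction)
            if verdict is None:
                continue
            growth, fmin, fmax, disabled = verdict
            if growth < growth_floor - 1e-9:
                continue
            if fmin > PRODUCTION_THRESHOLD:
                designs.append(
                    DeletionDesign(
                        deleted_genes=deleted,
                        disabled_reactions=disabled,
                        target_reaction_id=target_reaction,
                        predicted_growth=growth,
                        predicted_target_flux=fmax,
                        guaranteed_min_flux=fmin,
                    )
                )
    designs.sort(key=DeletionDesign.sort_key)
    return designs
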
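"""Linear-programming engine: FBA, pFBA, FVA, deletions, flux dissection.

All linear programs are delegated to the model's configured solver
through cobrapy; this module fixes the contracts the screen relies on
(tolerances, deletion semantics, degeneracy handling).

Degeneracy note: FBA optima are generally non-unique, so individual
flux values are only meaningful through FVA bounds or on a parsimonious
(minimum total flux) solution.  ``dissect_producing_fluxes`` therefore
expects a parsimonious solution when shares of production are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import cobra
from cobra.flux_analysis import flux_variability_analysis, pfba

from fruits.gsm_io import evaluate_gpr

#: Fluxes smaller than this (absolute) are reported as zero.
FLUX_EPSILON = 1e-9

#: Feasibility / optimality tolerance assumed from the LP solver.
SOLVER_TOLERANCE = 1e-6


@dataclass
class FluxSolution:
    """An FBA outcome: objective value, flux vector and solver status."""

    objective_value: float | None
    fluxes: Mapping[str, float] | None
    status: str  # "optimal" | "infeasible" | "unbounded" | other solver status

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """FVA result for one reaction at a fixed objective fraction."""

    reaction_id: str
    min_flux: float
    max_flux: float


def _clean(value: float) -> float:
    return 0.0 if abs(value) < FLUX_EPSILON else float(value)


def fba(
    model: cobra.Model,
    objective_reaction: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux.

    Maximizes (or minimizes) the named reaction — the model's own
    objective when ``objective_reaction`` is None — subject to
    steady-state mass balance ``S·v = 0`` and the flux bounds.
    """
    with model:
        if objective_reaction is not None:
            model.objective = model.reactions.get_by_id(objective_reaction)
        model.objective_direction = "max" if sense == "max" else "min"
        solution = model.optimize()
        if solution.status != "optimal":
            return FluxSolution(None, None, solution.status)
        return FluxSolution(
            float(solution.objective_value),
            {rid: _clean(v) for rid, v in solution.fluxes.items()},
            "optimal",
        )


def parsimonious_fba(model: cobra.Model) -> FluxSolution:
    """Parsimonious FBA: minimum total |flux| at the optimal objective.

    Resolves alternate optima into a unique, reproducible reference flux
    distribution; the candidate-identification step and flux dissection
    operate on this.
    """
    try:
        solution = pfba(model)
    except Exception:
        return FluxSolution(None, None, "infeasible")
    objective_rxns = list(
        cobra.util.solver.linear_reaction_coefficients(model)
    )
    obj = sum(float(solution.fluxes[r.id]) for r in objective_rxns)
    return FluxSolution(
        obj, {rid: _clean(v) for rid, v in solution.fluxes.items()}, "optimal"
    )


def fva(
    model: cobra.Model,
    reaction_ids: Iterable[str] | None = None,
    objective_fraction: float = 1.0,
) -> list[FluxRange]:
    """Flux variability analysis at a fixed fraction of the optimum.

    For each reaction, the minimum and maximum attainable flux subject
    to the model objective being at least ``objective_fraction`` times
    its optimum.  At fraction 1.0 this is the strict-coupling test: a
    positive minimum through a product drain certifies that any optimal
    growth state secretes the product.
    """
    if not 0 < objective_fraction <= 1:
        raise ValueError("objective_fraction must be in (0, 1]")
    reaction_list = (
        None if reaction_ids is None
        else [model.reactions.get_by_id(r) for r in reaction_ids]
    )
    frame = flux_variability_analysis(
        model,
        reaction_list=reaction_list,
        fraction_of_optimum=objective_fraction,
        processes=1,
    )
    return [
        FluxRange(rid, _clean(row["minimum"]), _clean(row["maximum"]))
        for rid, row in frame.iterrows()
    ]


def disabled_reactions(model: cobra.Model, genes: Iterable[str]) -> set[str]:
    """Reactions whose GPR evaluates false when ``genes`` are deleted."""
    deleted = set(genes)
    known = {g.id for g in model.genes}
    unknown = deleted - known
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    out: set[str] = set()
    for rxn in model.reactions:
        if rxn.gene_reaction_rule and deleted & {g.id for g in rxn.genes}:
            if not evaluate_gpr(rxn.gpr, deleted):
                out.add(rxn.id)
    return out


def knock_out(model: cobra.Model, genes: Iterable[str]) -> set[str]:
    """Zero the bounds of all reactions disabled by the gene deletions.

    Mutates the model (use inside ``with model:`` for reversibility);
    returns the set of disabled reaction ids.  Reactions with an empty
    GPR are never touched.
    """
    disabled = disabled_reactions(model, genes)
    for rid in disabled:
        model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return disabled


def apply_deletions(model: cobra.Model, genes: Iterable[str]) -> cobra.Model:
    """Return a copy of the model with the gene deletions applied."""
    mutant = model.copy()
    knock_out(mutant, genes)
    return mutant


def dissect_producing_fluxes(
    solution: FluxSolution,
    model: cobra.Model,
    metabolite_id: str,
) -> dict[str, float]:
    """Share of each reaction in the total production of a metabolite.

    For every reaction with positive net production (stoichiometric
    coefficient × flux > 0) in the given solution, its fraction of total
    production.  Fractions sum to 1 within 1e-6.  Returns an empty map
    when nothing produces the metabolite.  Meaningful on a parsimonious
    solution (alternate optima otherwise make shares arbitrary).
    """
    if not solution.optimal:
        raise ValueError("flux dissection requires an optimal solution")
    met = model.metabolites.get_by_id(metabolite_id)
    production: dict[str, float] = {}
    for rxn in met.reactions:
        flux = solution.fluxes.get(rxn.id, 0.0)
        rate = rxn.metabolites[met] * flux
        if rate > FLUX_EPSILON:
            production[rxn.id] = rate
    total = sum(production.values())
    if total <= FLUX_EPSILON:
        return {}
    return {rid: rate / total for rid, rate in production.items()}
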
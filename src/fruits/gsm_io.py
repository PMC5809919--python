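"""Genome-scale model I/O and editing.

Models are held as :class:`cobra.Model` objects — the standard container
for constraint-based metabolic analysis in Python.  This module wraps
the handful of operations the screen needs on top of that container:
SBML round-trips (FBC-v2 bounds/GPR primary, legacy-notes GPR accepted
by the underlying reader), Hill-formula parsing, boolean evaluation of
gene-protein-reaction (GPR) rules under knockouts, sink insertion and
directionality edits.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

import cobra
from cobra.core.gene import GPR
from cobra.util.solver import linear_reaction_coefficients

logger = logging.getLogger(__name__)

#: "Unbounded" drain capacity for inserted sinks, mmol gDW^-1 h^-1.
#: Matches the customary bound magnitude in genome-scale models.
DEFAULT_SINK_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """Raised when a loaded model violates structural invariants."""


def load_model(path: str, validate: bool = True) -> cobra.Model:
    """Read an SBML model (Level 2/3, FBC or legacy dialect).

    Parameters
    ----------
    path:
        SBML file.  Bounds and GPR rules are taken from the fbc package
        when present, otherwise from legacy notes/kinetic-law fields.
    validate:
        Check structural invariants (objective present, bounds ordered)
        and log a load summary.

    Raises
    ------
    ModelValidationError
        If the model defines no objective reaction or has inverted
        bounds.  SBML parse failures propagate from the reader and name
        the offending element.
    """
    model = cobra.io.read_sbml_model(path)
    if validate:
        problems = validate_model(model)
        if problems:
            raise ModelValidationError(
                f"model '{model.id}' failed validation: " + "; ".join(problems)
            )
        summary = summarize_model(model)
        logger.info(
            "loaded model %s: %d metabolites, %d reactions, %d genes",
            model.id, summary["n_metabolites"], summary["n_reactions"],
            summary["n_genes"],
        )
    return model


def write_model(model: cobra.Model, path: str) -> None:
    """Write a model as SBML Level 3 with fbc bounds and GPRs."""
    cobra.io.write_sbml_model(model, path)


def validate_model(model: cobra.Model) -> list[str]:
    """Return a list of invariant violations (empty when sound)."""
    problems: list[str] = []
    if not linear_reaction_coefficients(model):
        problems.append("no objective reaction is defined")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            problems.append(f"reaction {rxn.id} has lower bound > upper bound")
        if not rxn.metabolites:
            problems.append(f"reaction {rxn.id} has empty stoichiometry")
    return problems


def summarize_model(model: cobra.Model) -> dict:
    """Load summary: entity counts plus warnings (e.g. missing formulas).

    JSON-serializable; printed by the command-line loader.
    """
    missing_formula = sorted(
        m.id for m in model.metabolites if not m.formula
    )
    objective = list(linear_reaction_coefficients(model))
    return {
        "model_id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes),
        "objective_reaction": objective[0].id if objective else None,
        "warnings": (
            [f"{len(missing_formula)} metabolite(s) lack a chemical formula"]
            if missing_formula else []
        ),
        "metabolites_without_formula": missing_formula,
    }


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    >>> parse_formula("C2H3O2")
    {'C': 2, 'H': 3, 'O': 2}

    Raises
    ------
    ValueError
        If the string contains tokens that are not ``Element[count]``;
        the message carries the unparsed residue.
    """
    if formula is None:
        raise ValueError("formula is absent")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"unparseable formula {formula!r}: residue {formula[pos:]!r}"
            )
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(
            f"unparseable formula {formula!r}: residue {formula[pos:]!r}"
        )
    return counts


def carbon_count(metabolite: cobra.Metabolite) -> int | None:
    """Number of carbon atoms, or None when no formula is annotated."""
    if not metabolite.formula:
        return None
    return parse_formula(metabolite.formula).get("C", 0)


def evaluate_gpr(gpr: GPR | str | None, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR rule with the given genes deleted (set false).

    AND nodes model enzyme complexes (all subunits required), OR nodes
    isozymes (any suffices).  An empty rule means the reaction is not
    gene-associated and always evaluates true.
    """
    if gpr is None:
        return True
    if isinstance(gpr, str):
        gpr = GPR.from_string(gpr)
    return gpr.eval(knockouts=set(deleted))


def add_sink_reaction(
    model: cobra.Model,
    metabolite_id: str,
    bound: float = DEFAULT_SINK_BOUND,
) -> str:
    """Ensure the metabolite has a drain; return the drain's reaction id.

    If the metabolite already participates in a boundary reaction
    (exchange, demand or sink — any reaction touching only this
    metabolite with no counterpart), the model is left unchanged and the
    existing reaction id is returned.  Otherwise an irreversible sink
    ``SK_<metabolite_id>`` with bounds ``[0, bound]`` is appended in
    place.  Calling twice is a no-op.
    """
    try:
        met = model.metabolites.get_by_id(metabolite_id)
    except KeyError as exc:
        raise KeyError(f"unknown metabolite {metabolite_id!r}") from exc
    for rxn in met.reactions:
        if len(rxn.metabolites) == 1:
            return rxn.id
    sink = model.add_boundary(met, type="sink", lb=0.0, ub=bound)
    return sink.id


def set_reaction_irreversible(
    model: cobra.Model, reaction_id: str, direction: str = "forward"
) -> cobra.Model:
    """Clamp the bound opposing ``direction`` to zero, in place.

    ``direction="forward"`` sets ``lower_bound = max(lb, 0)``;
    ``"reverse"`` sets ``upper_bound = min(ub, 0)``.  Used e.g. to
    revise a reversible acetate kinase to its thermodynamically feasible
    direction.  Already-irreversible reactions are unchanged.
    """
    try:
        rxn = model.reactions.get_by_id(reaction_id)
    except KeyError as exc:
        raise KeyError(f"unknown reaction {reaction_id!r}") from exc
    if direction == "forward":
        if rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    elif direction == "reverse":
        if rxn.upper_bound > 0:
            rxn.upper_bound = 0.0
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    return model


def is_transport(reaction: cobra.Reaction) -> bool:
    """A reaction moving species between compartments (spans ≥ 2)."""
    return len({m.compartment for m in reaction.metabolites}) > 1


def strip_compartment(metabolite_id: str, compartments: Mapping | None = None) -> str:
    """Base species id with a trailing ``_<compartment>`` suffix removed."""
    if "_" not in metabolite_id:
        return metabolite_id
    base, _, tail = metabolite_id.rpartition("_")
    if compartments is not None and tail not in compartments:
        return metabolite_id
    if len(tail) <= 2:
        return base
    return metabolite_id
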
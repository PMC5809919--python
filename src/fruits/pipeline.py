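"""The full screen: candidates → trimming → OptKnock → coupling verdicts.

The screen walks a genome-scale model in five stages:

1. A parsimonious reference optimum (light- or substrate-limited) marks
   which reactions carry flux during balanced growth.
2. Flux-carrying non-exchange, non-transport reactions with two or more
   products are treated as anabolic; products that are not direct
   biomass substrates are preliminary side-product candidates.
3. The list is trimmed to carbon-containing non-cofactor metabolites.
4. Per candidate, a model copy gets an export route (existing drain,
   existing transporter + exchange, or a fresh sink), and gene-level
   OptKnock proposes a deletion set maximizing secretion at the inner
   biomass optimum.
5. FVA at the growth optimum certifies (or rejects) obligatory
   coupling; only certified candidates enter the report, ranked by
   carbon yield on biomass.

Candidate identification is deliberately permissive — OptKnock plus FVA
reject anything that cannot actually be coupled — because a candidate
filter based on "is consumed downstream" would discard exactly the
recycled side products the screen exists to find.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import cobra
import numpy as np
from cobra.util.solver import linear_reaction_coefficients
from scipy import stats

from fruits import cba_core, gsm_io
from fruits.optknock import (
    PRODUCTION_THRESHOLD,
    DeletionDesign,
    gene_optknock,
)

logger = logging.getLogger(__name__)

#: FVA strictness margin: |max - min| below this means the secretion
#: flux is pinned by the growth optimum.
STRICTNESS_TOLERANCE = 1e-6


def default_cofactor_list() -> frozenset[str]:
    """Base ids of energy/redox carriers excluded from candidacy.

    Shipped as an editable text file (one id per line, ``#`` comments);
    ids are matched case-insensitively against metabolite ids with and
    without their compartment suffix.
    """
    text = (
        resources.files("fruits").joinpath("data/cofactors.txt").read_text()
    )
    entries = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            entries.add(line)
    return frozenset(entries)


@dataclass
class FruitsConfig:
    """Tunable screen parameters.

    max_deletions:
        Deletion budget K per candidate (what a lab can realistically
        engineer; 4 by default).
    min_growth_fraction:
        Growth floor for OptKnock as a fraction of the wild-type
        optimum; 0.1 admits slow-growing designs but rejects
        non-growing ones.
    candidate_method:
        "flux" (reference-flux heuristic, model-agnostic) or
        "subsystem" (biosynthesis subsystem annotations).
    """

    max_deletions: int = 4
    min_growth_fraction: float = 0.1
    cofactor_list: frozenset[str] | None = None
    candidate_method: str = "flux"
    subsystem_keywords: tuple[str, ...] = (
        "biosynthesis", "synthesis", "anabolism",
    )
    flux_epsilon: float = 1e-6
    sink_bound: float = 1000.0
    big_m: float = 1000.0

    def cofactors(self) -> frozenset[str]:
        if self.cofactor_list is not None:
            return frozenset(x.lower() for x in self.cofactor_list)
        return default_cofactor_list()

    @classmethod
    def from_mapping(cls, data: dict) -> "FruitsConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if "cofactor_list" in known and known["cofactor_list"] is not None:
            known["cofactor_list"] = frozenset(known["cofactor_list"])
        if "subsystem_keywords" in known:
            known["subsystem_keywords"] = tuple(known["subsystem_keywords"])
        return cls(**known)


@dataclass
class CandidateSet:
    """Ordered candidate metabolites with their producing reactions."""

    metabolite_ids: list[str]
    provenance: dict[str, list[str]]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.metabolite_ids)

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in set(self.metabolite_ids)


@dataclass
class CouplingResult:
    """Per-candidate verdict of the strict-coupling test."""

    metabolite_id: str
    design: DeletionDesign | None
    growth_rate: float
    min_product_flux: float
    max_product_flux: float
    yield_on_biomass: float        # mmol gDW^-1 (= min flux / growth)
    cmol_yield: float | None       # C-mmol gDW^-1 (= yield × carbons)
    coupled: bool
    strict: bool


@dataclass
class Report:
    """Screen output: coupled products plus a full audit trail."""

    entries: list[CouplingResult]
    candidates: CandidateSet
    trimmed: CandidateSet
    wild_type_growth: float
    audit: dict

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.entries:
            rows.append({
                "metabolite": e.metabolite_id,
                "growth_rate_per_h": e.growth_rate,
                "yield_mmol_per_gDW": e.yield_on_biomass,
                "cmol_yield": e.cmol_yield,
                "min_flux": e.min_product_flux,
                "max_flux": e.max_product_flux,
                "strict": e.strict,
                "gene_knockouts": ", ".join(sorted(e.design.deleted_genes))
                if e.design else "",
                "alternate_knockouts": "; ".join(
                    ", ".join(sorted(alt)) for alt in e.design.alternates
                ) if e.design else "",
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _biomass_reaction(model: cobra.Model) -> cobra.Reaction:
    objective = list(linear_reaction_coefficients(model))
    if len(objective) != 1:
        raise ValueError("model must have exactly one objective reaction")
    return objective[0]


def find_side_products(
    model: cobra.Model,
    reference_solution: cba_core.FluxSolution | None = None,
    config: FruitsConfig | None = None,
) -> CandidateSet:
    """Identify co-products of flux-carrying anabolic reactions.

    With the default "flux" method, anabolic reactions are those
    carrying flux in the parsimonious reference optimum, excluding
    exchanges, transports and the biomass reaction itself.  Reactions
    producing two or more metabolites (in their flux direction) are
    co-producing; every such product that is not a direct biomass
    substrate becomes a candidate.  The "subsystem" method instead
    selects reactions whose subsystem annotation matches biosynthesis
    keywords.
    """
    config = config or FruitsConfig()
    if reference_solution is None:
        reference_solution = cba_core.parsimonious_fba(model)
    if not reference_solution.optimal:
        raise ValueError("reference solution is not optimal")
    eps = config.flux_epsilon
    biomass = _biomass_reaction(model)
    biomass_substrates = {
        m.id for m, c in biomass.metabolites.items() if c < 0
    }

    provenance: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if rxn.id == biomass.id or rxn.boundary or gsm_io.is_transport(rxn):
            continue
        flux = reference_solution.fluxes.get(rxn.id, 0.0)
        if config.candidate_method == "subsystem":
            subsystem = (rxn.subsystem or "").lower()
            if not any(k in subsystem for k in config.subsystem_keywords):
                continue
            direction = 1.0 if flux >= 0 else -1.0
        else:
            if abs(flux) <= eps:
                continue
            direction = 1.0 if flux > 0 else -1.0
        products = [
            m for m, c in rxn.metabolites.items() if c * direction > 0
        ]
        if len(products) < 2:
            continue
        for met in products:
            if met.id in biomass_substrates:
                continue
            provenance.setdefault(met.id, []).append(rxn.id)
    ordered = sorted(provenance)
    return CandidateSet(ordered, {m: provenance[m] for m in ordered})


def trim_candidates(
    candidates: CandidateSet,
    model: cobra.Model,
    cofactor_list: frozenset[str] | None = None,
) -> CandidateSet:
    """Keep carbon-containing, non-cofactor candidates.

    Metabolites without a formula annotation are dropped with a warning
    (their carbon content cannot be verified).
    """
    cofactors = (
        frozenset(x.lower() for x in cofactor_list)
        if cofactor_list is not None else default_cofactor_list()
    )
    kept: list[str] = []
    warnings: list[str] = []
    for met_id in candidates.metabolite_ids:
        met = model.metabolites.get_by_id(met_id)
        names = {
            met_id.lower(),
            gsm_io.strip_compartment(met_id, model.compartments).lower(),
        }
        if names & cofactors:
            continue
        carbons = gsm_io.carbon_count(met)
        if carbons is None:
            warnings.append(
                f"{met_id}: no formula annotation, excluded from candidacy"
            )
            logger.warning("candidate %s has no formula; excluded", met_id)
            continue
        if carbons < 1:
            continue
        kept.append(met_id)
    return CandidateSet(
        kept, {m: candidates.provenance[m] for m in kept}, warnings
    )


def ensure_export_route(
    model: cobra.Model, metabolite_id: str, sink_bound: float = 1000.0
) -> str:
    """Reaction id through which the metabolite can leave the system.

    Preference order: an existing drain on the metabolite itself; the
    exchange of a one-hop transport partner in another compartment; a
    newly inserted irreversible sink.  The model is only modified in the
    last case.
    """
    met = model.metabolites.get_by_id(metabolite_id)
    for rxn in met.reactions:
        if len(rxn.metabolites) == 1:
            return rxn.id
    for rxn in met.reactions:
        if not gsm_io.is_transport(rxn):
            continue
        for partner in rxn.metabolites:
            if partner.compartment == met.compartment:
                continue
            for drain in partner.reactions:
                if len(drain.metabolites) == 1:
                    return drain.id
    return gsm_io.add_sink_reaction(model, metabolite_id, bound=sink_bound)


def verify_coupling(
    model: cobra.Model,
    design: DeletionDesign | frozenset[str] | set[str],
    target_reaction: str,
) -> CouplingResult:
    """Apply the deletions, then test obligatory secretion by FBA + FVA.

    Growth is the FBA optimum of the deletion model; the target drain's
    FVA range at 100% of that optimum gives the guaranteed minimum and
    the attainable maximum secretion.  ``coupled`` requires the minimum
    to exceed 1e-6; ``strict`` additionally requires min ≈ max (the
    secretion flux is fully determined by growth).  An infeasible
    deletion model yields an uncoupled result with zero growth.
    """
    genes = (
        design.deleted_genes if isinstance(design, DeletionDesign)
        else frozenset(design)
    )
    target = model.reactions.get_by_id(target_reaction)
    met = (
        next(iter(target.metabolites))
        if len(target.metabolites) == 1 else None
    )
    met_id = met.id if met is not None else target_reaction
    carbons = gsm_io.carbon_count(met) if met is not None else None
    design_obj = design if isinstance(design, DeletionDesign) else None

    with model:
        cba_core.knock_out(model, genes)
        growth = model.slim_optimize(error_value=None)
        if growth is None or growth <= PRODUCTION_THRESHOLD:
            return CouplingResult(
                met_id, design_obj, 0.0, 0.0, 0.0, 0.0,
                0.0 if carbons is not None else None, False, False,
            )
        ranges = cba_core.fva(model, [target_reaction], objective_fraction=1.0)
    rng = ranges[0]
    growth = float(growth)
    yield_on_biomass = rng.min_flux / growth
    cmol = yield_on_biomass * carbons if carbons is not None else None
    return CouplingResult(
        metabolite_id=met_id,
        design=design_obj,
        growth_rate=growth,
        min_product_flux=rng.min_flux,
        max_product_flux=rng.max_flux,
        yield_on_biomass=yield_on_biomass,
        cmol_yield=cmol,
        coupled=rng.min_flux > PRODUCTION_THRESHOLD,
        strict=abs(rng.max_flux - rng.min_flux) < STRICTNESS_TOLERANCE,
    )


def run_fruits(
    model: cobra.Model, config: FruitsConfig | None = None
) -> Report:
    """Run the complete screen; never aborts on a single bad candidate.

    Returns a report listing only coupled products, sorted by carbon
    yield on biomass (descending, ties by metabolite id), along with the
    candidate sets and an audit of every rejected or failed candidate.
    """
    config = config or FruitsConfig()
    wt = cba_core.fba(model)
    if not wt.optimal:
        raise ValueError("model is infeasible under its default constraints")
    reference = cba_core.parsimonious_fba(model)
    candidates = find_side_products(model, reference, config)
    trimmed = trim_candidates(candidates, model, config.cofactor_list)

    entries: list[CouplingResult] = []
    audit: dict = {
        "examined": list(trimmed.metabolite_ids),
        "trimmed_out": sorted(
            set(candidates.metabolite_ids) - set(trimmed.metabolite_ids)
        ),
        "no_design": [],
        "not_coupled": [],
        "errors": {},
    }
    for met_id in trimmed.metabolite_ids:
        try:
            scratch = model.copy()
            target = ensure_export_route(scratch, met_id, config.sink_bound)
            design = gene_optknock(
                scratch, target,
                max_deletions=config.max_deletions,
                min_growth_fraction=config.min_growth_fraction,
                big_m=config.big_m,
            )
            if design is None:
                audit["no_design"].append(met_id)
                continue
            result = verify_coupling(scratch, design, target)
            result.metabolite_id = met_id
            if result.coupled:
                entries.append(result)
            else:
                audit["not_coupled"].append(met_id)
        except Exception as exc:  # quarantine the candidate, not the screen
            logger.exception("candidate %s failed", met_id)
            audit["errors"][met_id] = str(exc)

    entries.sort(
        key=lambda e: (
            -(e.cmol_yield if e.cmol_yield is not None else -np.inf),
            e.metabolite_id,
        )
    )
    return Report(
        entries=entries,
        candidates=candidates,
        trimmed=trimmed,
        wild_type_growth=wt.objective_value,
        audit=audit,
    )


@dataclass
class YieldCurve:
    """Growth-rate / carbon-yield points with their rank correlation."""

    points: list[tuple[float, float]]
    spearman_rho: float | None
    warning: str | None = None


def cmol_yield_curve(report: Report | list[CouplingResult]) -> YieldCurve:
    """Growth rate vs C-mol yield across coupled products.

    The screen's characteristic trade-off: the more carbon a design
    diverts to product per unit biomass, the slower it grows, so the
    Spearman rank correlation between growth and C-mol yield is
    expected to be negative.  Undefined correlations (single point,
    constant values) are flagged instead of silently propagated.
    """
    entries = report.entries if isinstance(report, Report) else report
    points = [
        (e.growth_rate, e.cmol_yield)
        for e in entries if e.cmol_yield is not None
    ]
    if not points:
        return YieldCurve([], None, "no coupled entries")
    if len(points) == 1:
        return YieldCurve(points, None, "correlation undefined for one point")
    growth, cmol = zip(*points)
    if len(set(growth)) == 1 or len(set(cmol)) == 1:
        return YieldCurve(
            list(points), 0.0,
            "constant values: correlation reported as 0",
        )
    rho = float(stats.spearmanr(growth, cmol).statistic)
    return YieldCurve(list(points), rho)
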
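"""Model I/O, formula parsing, GPR evaluation and model edits."""

import itertools

import pytest
from cobra import Metabolite, Model, Reaction
from cobra.io.sbml import CobraSBMLError

from fruits import cba_core, gsm_io

UNDECLARED_SPECIES_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="bad">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="GHOST" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>"""


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C2H3O2", {"C": 2, "H": 3, "O": 2}),
            ("HPO4", {"H": 1, "P": 1, "O": 4}),
            ("C10H12N5O3", {"C": 10, "H": 12, "N": 5, "O": 3}),
            ("Mg", {"Mg": 1}),
            ("C55H74N4O5Mg", {"C": 55, "H": 74, "N": 4, "O": 5, "Mg": 1}),
        ],
    )
    def test_hill_notation(self, formula, expected):
        assert gsm_io.parse_formula(formula) == expected

    def test_carbon_free_formula_has_zero_carbon(self):
        assert gsm_io.parse_formula("HPO4").get("C", 0) == 0

    @pytest.mark.parametrize("bad", ["C2H3O2-", "2CH4", "c2h4", "(CH2)n"])
    def test_unparseable_token_reports_residue(self, bad):
        with pytest.raises(ValueError, match="residue"):
            gsm_io.parse_formula(bad)

    def test_absent_formula_rejected(self):
        with pytest.raises(ValueError):
            gsm_io.parse_formula(None)


class TestEvaluateGpr:
    @pytest.mark.parametrize(
        "rule, deleted, expected",
        [
            ("g1 or g2", {"g1"}, True),
            ("g1 and g2", {"g1"}, False),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("(g1 and g2) or g3", {"g3"}, True),
            ("g1", {"g1"}, False),
            ("g1", set(), True),
            ("", set(), True),
        ],
    )
    def test_boolean_semantics(self, rule, deleted, expected):
        gpr = rule or None
        assert gsm_io.evaluate_gpr(gpr, deleted) is expected

    def test_no_deletions_always_active(self, mixed_toy):
        model, _ = mixed_toy
        for rxn in model.reactions:
            if rxn.gene_reaction_rule:
                assert gsm_io.evaluate_gpr(rxn.gpr, set()) is True


class TestSinkInsertion:
    def test_adds_one_irreversible_drain(self, canonical_toy):
        model, _ = canonical_toy
        n_before = len(model.reactions)
        sink = gsm_io.add_sink_reaction(model, "sp1_c")
        rxn = model.reactions.get_by_id(sink)
        assert len(model.reactions) == n_before + 1
        assert rxn.bounds == (0.0, gsm_io.DEFAULT_SINK_BOUND)
        assert list(rxn.metabolites.values()) == [-1]

    def test_idempotent(self, canonical_toy):
        model, _ = canonical_toy
        first = gsm_io.add_sink_reaction(model, "sp1_c")
        n_after = len(model.reactions)
        second = gsm_io.add_sink_reaction(model, "sp1_c")
        assert first == second
        assert len(model.reactions) == n_after

    def test_existing_drain_reused(self, canonical_toy):
        model, _ = canonical_toy
        # the external substrate already has its exchange reaction
        assert gsm_io.add_sink_reaction(model, "sub_e") == "EX_sub_e"

    def test_unknown_metabolite_errors(self, canonical_toy):
        model, _ = canonical_toy
        with pytest.raises(KeyError, match="nosuch"):
            gsm_io.add_sink_reaction(model, "nosuch")

    def test_zero_flux_sink_preserves_flux_space(self, canonical_toy):
        model, _ = canonical_toy
        before = cba_core.fba(model).objective_value
        gsm_io.add_sink_reaction(model, "sp1_c")
        after = cba_core.fba(model).objective_value
        assert after == pytest.approx(before, abs=1e-9)


class TestIrreversibility:
    def test_forward_clamps_lower_bound(self, canonical_toy):
        model, _ = canonical_toy
        rxn = model.reactions.get_by_id("REC1")
        rxn.bounds = (-1000, 1000)
        gsm_io.set_reaction_irreversible(model, "REC1", "forward")
        assert rxn.bounds == (0, 1000)

    def test_reverse_clamps_upper_bound(self, canonical_toy):
        model, _ = canonical_toy
        rxn = model.reactions.get_by_id("REC1")
        rxn.bounds = (-1000, 1000)
        gsm_io.set_reaction_irreversible(model, "REC1", "reverse")
        assert rxn.bounds == (-1000, 0)

    def test_already_irreversible_unchanged(self, canonical_toy):
        model, _ = canonical_toy
        rxn = model.reactions.get_by_id("REC1")
        assert rxn.bounds == (0, 1000)
        gsm_io.set_reaction_irreversible(model, "REC1", "forward")
        assert rxn.bounds == (0, 1000)

    def test_unknown_reaction_errors(self, canonical_toy):
        model, _ = canonical_toy
        with pytest.raises(KeyError):
            gsm_io.set_reaction_irreversible(model, "nope", "forward")


class TestSbmlRoundTrip:
    def test_stoichiometry_bounds_and_gpr_preserved(self, mixed_toy, tmp_path):
        model, _ = mixed_toy
        path = str(tmp_path / "toy.xml")
        gsm_io.write_model(model, path)
        reloaded = gsm_io.load_model(path)
        assert len(reloaded.metabolites) == len(model.metabolites)
        assert len(reloaded.reactions) == len(model.reactions)
        for rxn in model.reactions:
            twin = reloaded.reactions.get_by_id(rxn.id)
            assert twin.bounds == rxn.bounds
            assert {m.id: c for m, c in twin.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }
        # GPR semantics identical over every gene-state assignment
        genes = sorted(g.id for g in model.genes)
        for rxn in model.reactions:
            twin = reloaded.reactions.get_by_id(rxn.id)
            for r in range(len(genes) + 1):
                for deleted in itertools.combinations(genes, r):
                    assert gsm_io.evaluate_gpr(
                        rxn.gpr, set(deleted)
                    ) == gsm_io.evaluate_gpr(twin.gpr, set(deleted))

    def test_load_summary_counts(self, mixed_toy, tmp_path):
        model, _ = mixed_toy
        path = str(tmp_path / "toy.xml")
        gsm_io.write_model(model, path)
        summary = gsm_io.summarize_model(gsm_io.load_model(path))
        assert summary["n_reactions"] == len(model.reactions)
        assert summary["n_genes"] == 3
        assert summary["objective_reaction"] == "R_BIOMASS"
        assert summary["warnings"] == []

    def test_undeclared_species_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(UNDECLARED_SPECIES_SBML)
        with pytest.raises(CobraSBMLError):
            gsm_io.load_model(str(path))

    def test_missing_objective_is_rejected(self, tmp_path):
        model = Model("noobj")
        met = Metabolite("a_c", compartment="c")
        rxn = Reaction("R1", lower_bound=0, upper_bound=10)
        rxn.add_metabolites({met: -1})
        model.add_reactions([rxn])
        path = str(tmp_path / "noobj.xml")
        gsm_io.write_model(model, path)
        with pytest.raises(gsm_io.ModelValidationError, match="objective"):
            gsm_io.load_model(path)
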
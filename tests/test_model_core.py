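"""Model construction, parameter handling and validation diagnostics."""

import dataclasses

import pytest
import yaml

import brainenergy as be
from brainenergy.kinetics import LAW_FORMS
from brainenergy.model_core import (
    ConfigError,
    KineticLaw,
    ParameterResolutionError,
    Reaction,
    load_parameters,
    validate_model,
)

EXPECTED_VOLUMES = {0.033, 0.33, 0.0855, 0.019, 0.19, 0.0475, 0.2, 0.095}


class TestBuilders:
    def test_classical_has_eight_compartments_with_published_volumes(self, classical_model):
        assert len(classical_model.compartments) == 8
        assert {c.volume for c in classical_model.compartments.values()} == EXPECTED_VOLUMES
        assert classical_model.compartments["Am"].volume == 0.0475

    def test_classical_has_92_reactions(self, classical_model):
        assert len(classical_model.reactions) == 92
        assert classical_model.reaction_numbers == list(range(1, 93))

    def test_anlsh_membership_is_table_driven(self, anlsh_model):
        """The built ANLSH reaction set equals the variant config's
        enumeration (not a hard-coded list)."""
        from importlib import resources

        cfg = yaml.safe_load(
            resources.files("brainenergy.data").joinpath("model_anlsh.yaml").read_text()
        )
        assert sorted(anlsh_model.reaction_numbers) == sorted(cfg["reactions"])
        # the printed enumeration, spelled out
        expected = (
            list(range(1, 15)) + [16] + list(range(18, 27))
            + list(range(28, 49, 2)) + list(range(50, 57))
            + list(range(58, 69, 2)) + [70, 71] + list(range(73, 92, 2))
            + [93, 94]
        )
        assert anlsh_model.reaction_numbers == expected

    def test_anlsh_has_no_astrocyte_mitochondrial_reactions(self, anlsh_model):
        for r in anlsh_model.reactions:
            assert "Am" not in r.compartments(), r.number

    def test_anlsh_contains_shuttle_reactions_93_94(self, anlsh_model):
        r93 = anlsh_model.reaction(93)
        assert r93.source_compartment == "e" and r93.target_compartment == "Nc"
        r94 = anlsh_model.reaction(94)
        assert {s for s, _, _ in r94.substrates} == {"Lac", "NAD"}
        assert {s for s, _, _ in r94.products} == {"Pyr", "NADH"}

    def test_neuron_glucose_uptake_config_switch(self, params):
        default = be.build_anlsh_model(params)
        assert 15 not in default.reaction_numbers
        enabled = be.build_anlsh_model(params, options={"neuron_glucose_uptake": True})
        assert {15, 17} <= set(enabled.reaction_numbers)

    def test_classical_superset_of_anlsh_minus_shuttle(self, classical_model, anlsh_model):
        classical = set(classical_model.reaction_numbers)
        anlsh = set(anlsh_model.reaction_numbers) - {93, 94}
        assert anlsh < classical

    def test_builders_are_deterministic(self, params):
        m1, m2 = be.build_classical_model(params), be.build_classical_model(params)
        assert [r.number for r in m1.reactions] == [r.number for r in m2.reactions]
        assert list(m1.species) == list(m2.species)
        for r1, r2 in zip(m1.reactions, m2.reactions):
            assert r1 == r2
        for k in m1.species:
            assert m1.species[k] == m2.species[k]

    def test_all_laws_among_declared_forms(self, classical_model, anlsh_model):
        for model in (classical_model, anlsh_model):
            for r in model.reactions:
                assert r.law.form in LAW_FORMS

    def test_missing_parameter_names_reaction_and_parameter(self, params):
        broken = params.without(27, "v_max")
        with pytest.raises(ParameterResolutionError, match=r"27.*v_max"):
            be.build_classical_model(broken)

    def test_glycolysis_yields_two_three_carbon_units_per_glucose(self, classical_model):
        by_id = {s.key: s for s in classical_model.species.values()}
        assert by_id["Glc@Nc"].carbon == 6
        assert by_id["GAP@Nc"].carbon == 3
        pfk = classical_model.reaction(29)
        gap_stoich = {s: st for s, _, st in pfk.products}["GAP"]
        assert gap_stoich == 2.0
        # one glucose -> 2 GAP -> 2 pyruvate (3 carbons each)
        pk = classical_model.reaction(33)
        assert {s for s, _, _ in pk.products} >= {"Pyr"}
        assert by_id["Pyr@Nc"].carbon == 3

    def test_regulated_reactions_reference_declared_genes(self, classical_model):
        for model_gene in {r.regulated_by for r in classical_model.reactions if r.regulated_by}:
            assert model_gene in classical_model.genes


class TestParameterTable:
    def test_round_trip_entry_lookup(self, params):
        e = params.get(3, "gamma")
        assert e.unit == "1/min" and e.value > 0

    def test_shipped_config_resolves_every_classical_parameter(self, params):
        model = be.build_classical_model(params)  # raises if anything is missing
        for r in model.reactions:
            for name in r.law.required_params():
                assert (r.number, name) in params

    def test_negative_value_rejected_naming_key(self):
        doc = {"parameters": [
            {"reaction": 5, "name": "km", "value": -1.0, "unit": "mM",
             "provenance": "estimated"}]}
        with pytest.raises(ConfigError, match=r"5.*km"):
            load_parameters(yaml.safe_dump(doc))

    def test_duplicate_key_rejected(self):
        row = {"reaction": 5, "name": "km", "value": 1.0, "unit": "mM",
               "provenance": "estimated"}
        with pytest.raises(ConfigError, match="duplicate"):
            load_parameters(yaml.safe_dump({"parameters": [row, dict(row)]}))

    def test_unknown_unit_rejected(self):
        doc = {"parameters": [
            {"reaction": 5, "name": "km", "value": 1.0, "unit": "furlongs",
             "provenance": "estimated"}]}
        with pytest.raises(ConfigError, match="unit"):
            load_parameters(yaml.safe_dump(doc))

    def test_parse_failure(self):
        with pytest.raises(ConfigError):
            load_parameters("parameters: [::not yaml")

    def test_provenance_tags_present(self, params):
        tags = {e.provenance for e in params.entries()}
        assert tags <= {"supplementary", "literature_default", "estimated"}


class TestValidator:
    def test_shipped_variants_validate_clean(self, classical_model, anlsh_model, params):
        assert validate_model(classical_model, params).ok
        assert validate_model(anlsh_model, params).ok

    def test_ldh_missing_nadh_product_is_flagged(self, classical_model):
        model = dataclasses.replace(classical_model)
        model.reactions = list(classical_model.reactions)
        ldh = model.reaction(35)  # Pyr + NADH -> Lac + NAD
        broken = dataclasses.replace(
            ldh, products=tuple((s, c, st) for s, c, st in ldh.products if s != "NAD")
        )
        model.reactions[model.reactions.index(ldh)] = broken
        rep = validate_model(model)
        assert any("35" in line for line in rep.cofactor_imbalance)

    def test_dangling_species_is_flagged(self, classical_model):
        model = dataclasses.replace(classical_model)
        model.reactions = list(classical_model.reactions) + [
            Reaction(
                number=99, name="bogus",
                substrates=(("X", "Nc", 1.0),), products=(("CO2", "Nc", 1.0),),
                law=KineticLaw("mass_action", {"k": 1.0}),
                source_compartment="Nc", rate_species=(("X", "Nc"),),
            )
        ]
        rep = validate_model(model)
        assert any("X@Nc" in line for line in rep.dangling_species)

    def test_carbon_imbalance_is_flagged(self, classical_model):
        model = dataclasses.replace(classical_model)
        model.reactions = list(classical_model.reactions)
        pdh = model.reaction(70)  # Pyr + NAD -> AcCoA + CO2 + NADH
        broken = dataclasses.replace(
            pdh, products=tuple((s, c, st) for s, c, st in pdh.products if s != "CO2")
        )
        model.reactions[model.reactions.index(pdh)] = broken
        rep = validate_model(model)
        assert any("70" in line for line in rep.carbon_imbalance)

    def test_every_shipped_reaction_is_carbon_balanced(self, classical_model, anlsh_model):
        for model in (classical_model, anlsh_model):
            rep = validate_model(model)
            assert rep.carbon_imbalance == []
            assert rep.cofactor_imbalance == []
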
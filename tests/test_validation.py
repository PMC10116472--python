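"""Marginality, cardinality, ontology constraints, compilation, soundness."""

from __future__ import annotations

import re
from random import Random

import pytest

from schemaforge import (
    ClassDefinition,
    ContextMap,
    Curie,
    SchemaDocument,
    ValidationRuleSet,
    attach_ontology_constraint,
    build_class_graph,
    compile_validation,
    generate_example,
    random_schema,
    set_cardinality,
    set_marginality,
    validate_document,
)
from schemaforge.errors import (
    RuleError,
    UnknownPropertyError,
    UnsupportedKeywordError,
)
from schemaforge.fixtures import NCBI_TAXON
from schemaforge.schema_model import DEFAULT_PREFIXES
from schemaforge.validation import _validate_node, ontology_rule


def _ruleset(**kw) -> ValidationRuleSet:
    base = dict(
        rules={"name": {"type": "string"}, "citation": {"type": "string"}},
        required=(), recommended=(),
    )
    base.update(kw)
    return ValidationRuleSet(class_id=Curie("ns", "Widget"), **base)


def _instance(**fields) -> dict:
    return {"@context": {}, "@type": "ns:Widget", **fields}


class TestMarginality:
    def test_required_absence_invalidates(self):
        rs = set_marginality(_ruleset(), "name", "required")
        assert not validate_document(_instance(), rs).valid
        assert validate_document(_instance(name="x"), rs).valid

    def test_optional_absence_is_fine(self):
        rs = _ruleset()
        assert validate_document(_instance(), rs).valid

    def test_recommended_absence_warns_but_stays_valid(self):
        rs = set_marginality(_ruleset(), "name", "recommended")
        report = validate_document(_instance(), rs)
        assert report.valid
        assert any("name" in path for path, _ in report.warnings)

    def test_levels_are_exclusive(self):
        rs = set_marginality(_ruleset(), "name", "required")
        rs = set_marginality(rs, "name", "recommended")
        assert rs.marginality("name") == "recommended"
        rs = set_marginality(rs, "name", "optional")
        assert rs.marginality("name") == "optional"

    def test_unknown_property_is_refused(self):
        with pytest.raises(UnknownPropertyError):
            set_marginality(_ruleset(), "ghost", "required")


class TestCardinality:
    def test_many_accepts_scalar_and_list(self):
        rs = set_cardinality(_ruleset(), "citation", "many")
        assert validate_document(_instance(citation="a"), rs).valid
        assert validate_document(_instance(citation=["a", "b"]), rs).valid
        assert not validate_document(_instance(citation=[]), rs).valid

    def test_one_rejects_lists(self):
        rs = set_cardinality(_ruleset(), "citation", "one")
        assert validate_document(_instance(citation="a"), rs).valid
        assert not validate_document(_instance(citation=["a"]), rs).valid

    def test_many_is_idempotent_not_nested(self):
        rs1 = set_cardinality(_ruleset(), "citation", "many")
        rs2 = set_cardinality(rs1, "citation", "many")
        assert rs1.rules["citation"] == rs2.rules["citation"]
        assert set_cardinality(rs2, "citation", "one").rules["citation"] == {"type": "string"}

    def test_cardinality_never_changes_required_set(self):
        rs = set_marginality(_ruleset(), "citation", "required")
        toggled = set_cardinality(set_cardinality(rs, "citation", "many"), "citation", "one")
        assert toggled.required == rs.required
        assert toggled.recommended == rs.recommended

    def test_marginality_never_changes_value_rules(self):
        rs = set_cardinality(_ruleset(), "citation", "many")
        toggled = set_marginality(set_marginality(rs, "citation", "required"),
                                  "citation", "optional")
        assert toggled.rules == rs.rules

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs_match_two_branch_oracle(self, seed):
        """Acceptance under "many" equals testing the branches independently."""
        rng = Random(seed)
        scalar_rules = [{"type": "string"}, {"type": "integer"},
                        {"type": "string", "pattern": "^[a-z]+$"},
                        {"enum": ["x", "y"]}]
        values = ["abc", "XYZ", 7, True, None, [], ["abc"], ["abc", 5], [7, 9],
                  {"a": 1}, "x", ["x", "y"]]
        for _ in range(50):
            scalar = rng.choice(scalar_rules)
            wrapped = set_cardinality(
                ValidationRuleSet(rules={"p": dict(scalar)}), "p", "many"
            ).rules["p"]
            value = rng.choice(values)
            got = not _validate_node(value, wrapped, {}, "p")
            scalar_ok = not _validate_node(value, scalar, {}, "p")
            array_ok = (isinstance(value, list) and len(value) >= 1
                        and all(not _validate_node(v, scalar, {}, "p") for v in value))
            assert got == ((scalar_ok + array_ok) == 1), (scalar, value)


class TestOntologyConstraint:
    def test_ncbitaxon_curie_validates_free_text_does_not(self):
        rs = attach_ontology_constraint(_ruleset(), "name", NCBI_TAXON)
        ok = _instance(name={"identifier": "NCBITaxon:2697049"})
        iri = _instance(name={"identifier":
                              "http://purl.obolibrary.org/obo/NCBITaxon_2697049"})
        bad = _instance(name="severe acute respiratory syndrome coronavirus 2")
        assert validate_document(ok, rs).valid
        assert validate_document(iri, rs).valid
        assert not validate_document(bad, rs).valid

    def test_empty_ontology_spec_is_refused(self):
        with pytest.raises(RuleError):
            attach_ontology_constraint(_ruleset(), "name", {})

    def test_random_identifiers_match_regex_oracle(self):
        rs = attach_ontology_constraint(_ruleset(), "name", NCBI_TAXON)
        rng = Random(0)
        alphabet = "NCBITaxon:0123456789abc _%/"
        curie_re = re.compile(r"^NCBITaxon:[0-9]+$")
        iri_re = re.compile(r"^http://purl\.obolibrary\.org/obo/NCBITaxon_[0-9]+$")
        for i in range(100):
            if i % 3 == 0:
                ident = "NCBITaxon:" + "".join(
                    rng.choice("0123456789x") for _ in range(rng.randint(1, 8)))
            else:
                ident = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 20)))
            expected = bool(curie_re.match(ident) or iri_re.match(ident))
            got = validate_document(_instance(name={"identifier": ident}), rs).valid
            assert got == expected, ident


class TestCompilation:
    def _docs(self, parent_rs, child_rs):
        ctx = ContextMap({**DEFAULT_PREFIXES, "ns": "https://example.org/ns/"})
        from schemaforge import PropertyDefinition

        parent, child = Curie("ns", "Parent"), Curie("ns", "Child")
        doc = SchemaDocument(
            namespace="ns", context=ctx,
            classes=(ClassDefinition(id=parent, validation=parent_rs),
                     ClassDefinition(id=child, sub_class_of=(parent,),
                                     validation=child_rs)),
            properties=(
                PropertyDefinition(id=Curie("ns", "alpha"), domain_includes=(parent,)),
                PropertyDefinition(id=Curie("ns", "beta"), domain_includes=(child,)),
            ),
        )
        return [doc], build_class_graph([doc])

    def test_no_ancestor_validation_is_identity(self):
        rs = ValidationRuleSet(rules={"beta": {"type": "string"}}, required=("beta",))
        docs, graph = self._docs(None, rs)
        compiled = compile_validation(graph, docs, Curie("ns", "Child"))
        assert compiled.rules == rs.rules
        assert compiled.required == rs.required

    def test_required_sets_union_down_the_chain(self):
        parent = ValidationRuleSet(rules={"alpha": {"type": "string"}}, required=("alpha",))
        child = ValidationRuleSet(rules={"beta": {"type": "integer"}}, required=("beta",))
        docs, graph = self._docs(parent, child)
        compiled = compile_validation(graph, docs, Curie("ns", "Child"))
        assert set(compiled.required) == {"alpha", "beta"}

    def test_child_most_rule_wins_conflicts(self):
        parent = ValidationRuleSet(rules={"alpha": {"type": "string"}})
        child = ValidationRuleSet(rules={"alpha": {"type": "integer"}})
        docs, graph = self._docs(parent, child)
        compiled = compile_validation(graph, docs, Curie("ns", "Child"))
        assert compiled.rules["alpha"] == {"type": "integer"}

    def test_required_monotone_along_chain(self):
        parent = ValidationRuleSet(rules={"alpha": {"type": "string"}}, required=("alpha",))
        docs, graph = self._docs(parent, None)
        child_c = compile_validation(graph, docs, Curie("ns", "Child"))
        parent_c = compile_validation(graph, docs, Curie("ns", "Parent"))
        assert set(parent_c.required) <= set(child_c.required)

    def test_rule_outside_effective_set_is_refused(self):
        child = ValidationRuleSet(rules={"gamma": {"type": "string"}})
        docs, graph = self._docs(None, child)
        with pytest.raises(RuleError):
            compile_validation(graph, docs, Curie("ns", "Child"))

    def test_unsupported_keyword_fails_loudly(self):
        with pytest.raises(UnsupportedKeywordError):
            ValidationRuleSet(rules={"name": {"type": "string", "maxLength": 3}}).meta_validate()

    def test_compiled_outbreak_dataset_meta_validates(self, graph, all_docs):
        compiled = compile_validation(graph, all_docs, Curie("outbreak", "Dataset"))
        compiled.meta_validate()
        schema = compiled.to_json_schema()
        assert schema["$schema"].endswith("draft-07/schema#")
        assert "infectiousAgent" in schema["properties"]


class TestValidateDocument:
    def test_type_mismatch_is_a_violation_not_an_exception(self):
        rs = _ruleset()
        report = validate_document({"@type": "ns:Other"}, rs)
        assert not report.valid
        assert report.violations[0].path == "@type"

    def test_non_object_instance_raises(self):
        with pytest.raises(TypeError):
            validate_document(["not", "an", "object"], _ruleset())

    def test_unknown_properties_warn_only(self):
        report = validate_document(_instance(mystery=1), _ruleset())
        assert report.valid
        assert any("mystery" in p for p, _ in report.warnings)

    def test_at_keys_are_exempt(self):
        report = validate_document(_instance(**{"@id": "x"}), _ruleset())
        assert report.valid
        assert not report.warnings


class TestGenerateExample:
    def test_empty_ruleset_yields_bare_markup(self):
        rs = ValidationRuleSet(class_id=Curie("ns", "Widget"))
        out = generate_example(rs, Curie("ns", "Widget"), seed=1)
        assert set(out) == {"@context", "@type"}
        assert out["@type"] == "ns:Widget"

    def test_required_string_property_is_generated(self):
        rs = _ruleset(required=("name",))
        out = generate_example(rs, Curie("ns", "Widget"), seed=1)
        assert isinstance(out["name"], str)

    def test_deterministic_for_fixed_seed(self, graph, all_docs):
        compiled = compile_validation(graph, all_docs, Curie("outbreak", "Dataset"))
        a = generate_example(compiled, Curie("outbreak", "Dataset"), seed=7)
        b = generate_example(compiled, Curie("outbreak", "Dataset"), seed=7)
        assert a == b

    @pytest.mark.parametrize("seed", range(50))
    def test_soundness_pair_on_random_classes(self, seed):
        """Generated markup validates; deleting any required key invalidates."""
        doc = random_schema(seed, n_classes=4, n_props=8, rooted=False)
        graph = build_class_graph([doc])
        for cls in doc.classes:
            compiled = compile_validation(graph, [doc], cls.id)
            example = generate_example(compiled, cls.id, seed=seed)
            assert validate_document(example, compiled).valid
            for req in compiled.required:
                broken = {k: v for k, v in example.items() if k != req}
                assert not validate_document(broken, compiled).valid
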
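"""Class graph, ancestor chains, inheritance and rooting."""

from __future__ import annotations

import json

import pytest

from schemaforge import (
    ClassDefinition,
    ContextMap,
    Curie,
    PropertyDefinition,
    SchemaDocument,
    ancestor_chain,
    build_class_graph,
    effective_properties,
    is_rooted_in_schemaorg,
    random_schema,
)
from schemaforge.errors import (
    CycleError,
    DanglingParentWarning,
    DuplicateDefinitionError,
    UnknownClassError,
)
from schemaforge.schema_model import DEFAULT_PREFIXES

from conftest import oracle_chains, oracle_effective


def _doc(ns: str, classes, properties=()):
    ctx = ContextMap({**DEFAULT_PREFIXES, ns: f"https://example.org/{ns}/"})
    return SchemaDocument(namespace=ns, context=ctx, classes=tuple(classes),
                          properties=tuple(properties))


class TestGraphBuild:
    def test_every_outbreak_class_has_a_parent(self, graph, outbreak_doc):
        for cls in outbreak_doc.classes:
            assert graph.parents_of(cls.id), cls.id

    def test_single_parentless_class(self):
        doc = _doc("ns", [ClassDefinition(id=Curie("ns", "Solo"))])
        graph = build_class_graph([doc])
        assert graph.nodes == frozenset({Curie("ns", "Solo")})
        assert graph.parents_of(Curie("ns", "Solo")) == ()

    def test_cycle_is_rejected_naming_the_cycle(self):
        a, b, c = (Curie("ns", x) for x in "ABC")
        doc = _doc("ns", [
            ClassDefinition(id=a, sub_class_of=(b,)),
            ClassDefinition(id=b, sub_class_of=(c,)),
            ClassDefinition(id=c, sub_class_of=(a,)),
        ])
        with pytest.raises(CycleError) as err:
            build_class_graph([doc])
        assert set(err.value.cycle) == {"ns:A", "ns:B", "ns:C"}

    def test_conflicting_duplicate_definitions_rejected(self):
        d1 = _doc("ns", [ClassDefinition(id=Curie("ns", "A"), description="one")])
        d2 = _doc("ns", [ClassDefinition(id=Curie("ns", "A"), description="two")])
        with pytest.raises(DuplicateDefinitionError):
            build_class_graph([d1, d2])
        # identical duplicates are fine
        build_class_graph([d1, d1])

    def test_dangling_parent_warns_and_is_flagged(self):
        doc = _doc("ns", [ClassDefinition(id=Curie("ns", "A"),
                                          sub_class_of=(Curie("ns", "Ghost"),))])
        with pytest.warns(DanglingParentWarning):
            graph = build_class_graph([doc])
        assert Curie("ns", "Ghost") in graph.dangling

    def test_adjacency_export_is_json_serializable(self, graph):
        payload = graph.to_adjacency()
        parsed = json.loads(json.dumps(payload))
        assert "outbreak:Protocol" in parsed["edges"]


class TestAncestorChain:
    def test_protocol_chain_reaches_thing_through_howto(self, graph):
        chains = ancestor_chain(graph, Curie("outbreak", "Protocol"))
        assert chains == [[Curie("schema", "HowTo"), Curie("schema", "CreativeWork"),
                           Curie("schema", "Thing")]]

    def test_root_class_has_empty_chain(self, graph):
        assert ancestor_chain(graph, Curie("schema", "Thing")) == []

    def test_unknown_class_raises(self, graph):
        with pytest.raises(UnknownClassError):
            ancestor_chain(graph, Curie("nope", "Nope"))

    @pytest.mark.parametrize("seed", range(30))
    def test_random_dags_match_exhaustive_path_oracle(self, seed):
        doc = random_schema(seed, n_classes=10, n_props=0, rooted=False)
        graph = build_class_graph([doc])
        for cls in doc.classes:
            assert ancestor_chain(graph, cls.id) == oracle_chains([doc], cls.id)


class TestEffectiveProperties:
    def test_outbreak_dataset_inherits_and_extends(self, graph, all_docs):
        view = effective_properties(graph, all_docs, Curie("outbreak", "Dataset"))
        names = view.property_names()
        # every schema:Dataset effective property, plus the new one
        base = effective_properties(graph, all_docs, Curie("schema", "Dataset"))
        assert base.property_names() <= names
        assert "infectiousAgent" in names
        assert view.properties["infectiousAgent"].id == Curie("outbreak", "infectiousAgent")

    def test_parentless_class_without_properties_is_empty(self):
        doc = _doc("ns", [ClassDefinition(id=Curie("ns", "Solo"))])
        graph = build_class_graph([doc])
        assert effective_properties(graph, [doc], Curie("ns", "Solo")).properties == {}

    def test_shadowing_in_linear_chain_matches_union_with_override(self):
        a, b, c = (Curie("ns", x) for x in ("A", "B", "C"))
        doc = _doc(
            "ns",
            [ClassDefinition(id=c),
             ClassDefinition(id=b, sub_class_of=(c,)),
             ClassDefinition(id=a, sub_class_of=(b,))],
            [PropertyDefinition(id=Curie("ns", "sharedName"), domain_includes=(c,)),
             PropertyDefinition(id=Curie("ns", "other"), domain_includes=(c,)),
             # same local name re-declared child-most: must shadow C's
             PropertyDefinition(id=Curie("ns2", "sharedName"), domain_includes=(a,))],
        )
        doc = SchemaDocument(
            namespace="ns",
            context=doc.context.merged(ContextMap({"ns2": "https://example.org/ns2/"})),
            classes=doc.classes, properties=doc.properties,
        )
        graph = build_class_graph([doc])
        view = effective_properties(graph, [doc], a)
        assert view.properties["sharedName"].id == Curie("ns2", "sharedName")
        assert set(view.properties) == {"sharedName", "other"}
        assert view.properties == {
            k: next(p for p in doc.properties if p.id == v)
            for k, v in oracle_effective([doc], a).items()
        }

    @pytest.mark.parametrize("seed", range(30))
    def test_random_graphs_match_naive_traversal_oracle(self, seed):
        doc = random_schema(seed, n_classes=12, n_props=20, rooted=False)
        graph = build_class_graph([doc])
        for cls in doc.classes:
            got = {k: p.id for k, p in
                   effective_properties(graph, [doc], cls.id).properties.items()}
            assert got == oracle_effective([doc], cls.id)

    @pytest.mark.parametrize("seed", range(15))
    def test_monotonicity_along_every_subclass_edge(self, seed):
        doc = random_schema(seed, n_classes=12, n_props=20, rooted=False)
        graph = build_class_graph([doc])
        views = {c.id: effective_properties(graph, [doc], c.id) for c in doc.classes}
        for cls in doc.classes:
            for parent in cls.sub_class_of:
                if parent in views:
                    assert views[parent].property_names() <= views[cls.id].property_names()


class TestRooting:
    def test_all_outbreak_classes_are_rooted(self, graph, outbreak_doc):
        for cls in outbreak_doc.classes:
            assert is_rooted_in_schemaorg(graph, cls.id)

    def test_isolated_private_class_is_not_rooted(self):
        doc = _doc("priv", [ClassDefinition(id=Curie("priv", "Island"))])
        graph = build_class_graph([doc])
        assert not is_rooted_in_schemaorg(graph, Curie("priv", "Island"))

    def test_one_schema_parent_suffices_among_foreign_vocabularies(self, core_doc):
        # class built mostly from another vocabulary, but one chain reaches schema:
        ctx = ContextMap({**DEFAULT_PREFIXES,
                          "dcmi": "http://purl.org/dc/terms/",
                          "mix": "https://example.org/mix/"})
        doc = SchemaDocument(
            namespace="mix", context=ctx,
            classes=(
                ClassDefinition(id=Curie("dcmi", "BibliographicResource")),
                ClassDefinition(
                    id=Curie("mix", "Hybrid"),
                    sub_class_of=(Curie("dcmi", "BibliographicResource"),
                                  Curie("schema", "Thing")),
                ),
            ),
        )
        graph = build_class_graph([core_doc, doc])
        assert is_rooted_in_schemaorg(graph, Curie("mix", "Hybrid"))

    def test_dangling_schema_parent_is_a_dead_end(self):
        doc = _doc("ns", [ClassDefinition(id=Curie("ns", "A"),
                                          sub_class_of=(Curie("schema", "Ghost"),))])
        with pytest.warns(DanglingParentWarning):
            graph = build_class_graph([doc])
        assert not is_rooted_in_schemaorg(graph, Curie("ns", "A"))
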
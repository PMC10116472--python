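"""Schema-editor logic: extend an existing class, compose documents.

Extension follows reference semantics: the produced document contains *one*
new class whose ``rdfs:subClassOf`` points at the base class by CURIE, plus
any newly created properties with the new class as their domain.  Nothing is
copied from the base document — inherited properties stay inherited, so
upstream updates flow through.  Inherited properties "selected" in an
:class:`ExtensionRequest` appear only inside the new class's embedded
validation block (selection is about validation desirability, not structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .errors import ExtensionError, MergeError
from .hierarchy import build_class_graph, effective_properties, is_rooted_in_schemaorg
from .schema_model import (
    ClassDefinition,
    ContextMap,
    Curie,
    DEFAULT_PREFIXES,
    PropertyDefinition,
    SchemaDocument,
    namespace_iri,
)
from .validation import (
    ValidationRuleSet,
    attach_ontology_constraint,
    set_cardinality,
    set_marginality,
)

__all__ = ["ExtensionRequest", "extend_class", "merge_schemas"]


@dataclass(frozen=True, slots=True)
class ExtensionRequest:
    """Non-interactive description of a class extension (the editor form).

    ``selected`` names inherited properties that should carry validation in
    the new class; ``rules`` may override the default (unconstrained) rule per
    selected/new property; ``cardinality`` and ``ontology`` apply the
    corresponding rule transformations.
    """

    base: Curie
    namespace: str
    name: str
    description: str = ""
    principal: bool = False
    selected: tuple[str, ...] = ()
    new_properties: tuple[PropertyDefinition, ...] = ()
    rules: dict[str, dict] = field(default_factory=dict)
    required: tuple[str, ...] = ()
    recommended: tuple[str, ...] = ()
    cardinality: dict[str, str] = field(default_factory=dict)
    ontology: dict[str, dict] = field(default_factory=dict)

    @property
    def class_id(self) -> Curie:
        return Curie(self.namespace, self.name)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExtensionRequest":
        for key in ("base", "namespace", "name"):
            if key not in raw:
                raise ExtensionError(f"extension request is missing {key!r}")
        new_props = []
        target = Curie(raw["namespace"], raw["name"])
        for spec in raw.get("new_properties", ()):
            if "name" not in spec:
                raise ExtensionError("each new property needs a 'name'")
            new_props.append(
                PropertyDefinition(
                    id=Curie(raw["namespace"], spec["name"]),
                    label=spec.get("label", ""),
                    description=spec.get("description", ""),
                    domain_includes=(target,),
                    range_includes=tuple(Curie.parse(r) for r in spec.get("range", ["schema:Text"])),
                )
            )
        return cls(
            base=Curie.parse(raw["base"]),
            namespace=raw["namespace"],
            name=raw["name"],
            description=raw.get("description", ""),
            principal=bool(raw.get("principal", False)),
            selected=tuple(raw.get("selected", ())),
            new_properties=tuple(new_props),
            rules={k: dict(v) for k, v in raw.get("rules", {}).items()},
            required=tuple(raw.get("required", ())),
            recommended=tuple(raw.get("recommended", ())),
            cardinality=dict(raw.get("cardinality", {})),
            ontology={k: dict(v) for k, v in raw.get("ontology", {}).items()},
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ExtensionRequest":
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ExtensionError("extension config must be a mapping")
        return cls.from_dict(raw)


def _build_ruleset(request: ExtensionRequest, covered: list[str]) -> ValidationRuleSet | None:
    stray = set(request.rules) - set(covered)
    if stray:
        raise ExtensionError(f"rules given for unknown properties: {sorted(stray)}")
    rules = {name: dict(request.rules.get(name, {})) for name in covered}
    if not rules:
        return None
    ruleset = ValidationRuleSet(rules=rules)
    for name in request.required:
        ruleset = set_marginality(ruleset, name, "required")
    for name in request.recommended:
        ruleset = set_marginality(ruleset, name, "recommended")
    for name, arity in request.cardinality.items():
        ruleset = set_cardinality(ruleset, name, arity)
    for name, ontology in request.ontology.items():
        ruleset = attach_ontology_constraint(ruleset, name, ontology)
    ruleset.meta_validate()
    return ruleset


def extend_class(docs: Iterable[SchemaDocument], request: ExtensionRequest) -> SchemaDocument:
    """Create a new document extending ``request.base`` — pure, inputs unchanged."""
    docs = list(docs)
    graph = build_class_graph(docs)
    graph.require(request.base)
    if not is_rooted_in_schemaorg(graph, request.base):
        raise ExtensionError(f"base class {request.base} is not rooted in Schema.org")

    target = request.class_id
    for doc in docs:
        if target in doc.class_ids() or target in doc.property_ids():
            raise ExtensionError(f"{target} is already defined (in namespace {doc.namespace!r})")

    base_view = effective_properties(graph, docs, request.base)
    missing = set(request.selected) - base_view.property_names()
    if missing:
        raise ExtensionError(
            f"selected properties not in the effective set of {request.base}: {sorted(missing)}"
        )
    new_names = [p.id.local for p in request.new_properties]
    collisions = set(new_names) & set(request.selected)
    if collisions:
        raise ExtensionError(f"new properties collide with selected names: {sorted(collisions)}")

    context = ContextMap(DEFAULT_PREFIXES)
    for doc in docs:
        context = context.merged(doc.context)
    if request.namespace not in context:
        context.bind(request.namespace, namespace_iri(request.namespace))

    ruleset = _build_ruleset(request, list(request.selected) + new_names)
    new_class = ClassDefinition(
        id=target,
        label=request.name,
        description=request.description,
        sub_class_of=(request.base,),
        validation=ruleset,
        principal=request.principal,
    )
    out = SchemaDocument(
        namespace=request.namespace,
        context=context,
        classes=(new_class,),
        properties=tuple(request.new_properties),
    )
    out.validate()
    return out


def merge_schemas(docs: list[SchemaDocument], namespace: str) -> SchemaDocument:
    """Merge documents into one namespace; duplicates must agree exactly.

    Document order is preserved; identical duplicate definitions collapse to
    one occurrence; conflicting duplicates and conflicting prefix bindings are
    refused rather than renamed.
    """
    if not docs:
        raise MergeError("nothing to merge")
    context = ContextMap()
    for doc in docs:
        context = context.merged(doc.context)
    if namespace not in context:
        context.bind(namespace, namespace_iri(namespace))

    classes: list[ClassDefinition] = []
    properties: list[PropertyDefinition] = []
    seen: dict[Curie, object] = {}
    for doc in docs:
        for node in (*doc.classes, *doc.properties):
            if node.id in seen:
                if seen[node.id] != node:
                    raise MergeError(f"conflicting definitions of {node.id}")
                continue
            seen[node.id] = node
            if isinstance(node, ClassDefinition):
                classes.append(node)
            else:
                properties.append(node)

    out = SchemaDocument(
        namespace=namespace,
        context=context,
        classes=tuple(classes),
        properties=tuple(properties),
    )
    out.validate()
    return out
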
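"""Data model, parsing and canonical serialization of JSON-LD schema documents.

A schema document describes one namespace's worth of classes and properties in
the RDF Schema style used by Schema.org's own vocabulary dump: a ``@context``
binding CURIE prefixes to IRI bases, followed by a ``@graph`` of nodes typed
``rdfs:Class`` or ``rdf:Property``.  Classes may carry an embedded block of
JSON Schema validation rules under the ``$validation`` key (see
:mod:`schemaforge.validation`), plus a boolean ``x:principal`` annotation
marking top-level resource types.  One extra annotation, ``x:namespace``,
records the document's namespace token explicitly so that documents composed
from several vocabularies (see :func:`schemaforge.authoring.merge_schemas`)
still round-trip losslessly.

Serialization is canonical: fixed top-level and per-node key order, two-space
indent, UTF-8, classes before properties in document order.  ``parse_schema``
and ``serialize_schema`` are exact inverses on canonical form, and serializing
the same document twice is byte-identical — this is what makes the file-backed
registry and the CLI diffable and reproducible.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace

from .errors import (
    ContextError,
    InvariantError,
    MalformedDocumentError,
    MissingContextError,
    NamespaceError,
    NamingConventionWarning,
    NodeIdentifierError,
    UnknownNodeTypeWarning,
)

__all__ = [
    "Curie",
    "ContextMap",
    "PropertyDefinition",
    "ClassDefinition",
    "SchemaDocument",
    "parse_schema",
    "serialize_schema",
    "resolve_curie",
    "SCHEMA_ORG",
    "DEFAULT_PREFIXES",
    "namespace_iri",
]

SCHEMA_ORG = "https://schema.org/"

#: Prefixes bound in every context this package writes.  ``x`` namespaces the
#: non-RDF annotation keys (x:principal, x:namespace).
DEFAULT_PREFIXES = {
    "schema": SCHEMA_ORG,
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "x": "https://schemaforge.example.org/annotation/",
}

#: Reserved prefixes that never identify a document's own namespace.
RESERVED_PREFIXES = frozenset(DEFAULT_PREFIXES)

_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*://\S+$")
_UPPER_CAMEL_RE = re.compile(r"^[A-Z][A-Za-z0-9]*$")
_LOWER_CAMEL_RE = re.compile(r"^[a-z][A-Za-z0-9]*$")

_NODE_KEY_ORDER = (
    "@id",
    "@type",
    "rdfs:label",
    "rdfs:comment",
    "rdfs:subClassOf",
    "schema:domainIncludes",
    "schema:rangeIncludes",
    "x:principal",
    "$validation",
)


def namespace_iri(namespace: str) -> str:
    """Default IRI base synthesized for a namespace with no explicit binding."""
    return f"https://example.org/{namespace}/"


def is_absolute_iri(token: str) -> bool:
    return bool(_IRI_RE.match(token))


@dataclass(frozen=True, slots=True, order=True)
class Curie:
    """Compact IRI ``prefix:local``, resolvable through a :class:`ContextMap`."""

    prefix: str
    local: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"

    @classmethod
    def parse(cls, token: str) -> "Curie":
        if ":" not in token:
            raise ContextError(f"not a CURIE (no prefix separator): {token!r}")
        prefix, _, local = token.partition(":")
        if not prefix:
            raise ContextError(f"empty prefix in CURIE {token!r}")
        if not local:
            raise ContextError(f"empty local name in CURIE {token!r}")
        return cls(prefix, local)


class ContextMap:
    """Prefix → absolute IRI base map (the document's ``@context``)."""

    def __init__(self, prefixes: dict[str, str] | None = None):
        self._prefixes: dict[str, str] = {}
        for prefix, base in (prefixes or {}).items():
            self.bind(prefix, base)

    def bind(self, prefix: str, base: str) -> None:
        if not prefix or ":" in prefix:
            raise ContextError(f"invalid prefix {prefix!r}")
        if not is_absolute_iri(base):
            raise ContextError(f"IRI base for {prefix!r} is not absolute: {base!r}")
        existing = self._prefixes.get(prefix)
        if existing is not None and existing != base:
            raise ContextError(
                f"prefix {prefix!r} already bound to {existing!r}, cannot rebind to {base!r}"
            )
        self._prefixes[prefix] = base

    def __contains__(self, prefix: str) -> bool:
        return prefix in self._prefixes

    def __getitem__(self, prefix: str) -> str:
        try:
            return self._prefixes[prefix]
        except KeyError:
            raise ContextError(f"unknown prefix {prefix!r}") from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ContextMap) and self._prefixes == other._prefixes

    def __repr__(self) -> str:
        return f"ContextMap({self._prefixes!r})"

    def prefixes(self) -> dict[str, str]:
        return dict(self._prefixes)

    def merged(self, other: "ContextMap") -> "ContextMap":
        """Union of two contexts; conflicting bindings raise ContextError."""
        out = ContextMap(self._prefixes)
        for prefix, base in other._prefixes.items():
            out.bind(prefix, base)
        return out

    def copy(self) -> "ContextMap":
        return ContextMap(self._prefixes)


def resolve_curie(context: ContextMap, token: str) -> str:
    """Expand a CURIE to an absolute IRI; absolute IRIs pass through unchanged."""
    if is_absolute_iri(token):
        return token
    curie = Curie.parse(token)
    return context[curie.prefix] + curie.local


@dataclass(frozen=True, slots=True)
class PropertyDefinition:
    """An ``rdf:Property`` node: a named attribute of one or more classes."""

    id: Curie
    label: str = ""
    description: str = ""
    domain_includes: tuple[Curie, ...] = ()
    range_includes: tuple[Curie, ...] = ()

    def __post_init__(self):
        if not self.domain_includes:
            raise InvariantError(f"property {self.id} has empty domainIncludes")
        if not self.label:
            object.__setattr__(self, "label", self.id.local)


@dataclass(frozen=True, slots=True)
class ClassDefinition:
    """An ``rdfs:Class`` node, optionally carrying embedded validation rules."""

    id: Curie
    label: str = ""
    description: str = ""
    sub_class_of: tuple[Curie, ...] = ()
    validation: "object | None" = None  # ValidationRuleSet; kept loose to avoid a cycle
    principal: bool = False

    def __post_init__(self):
        if any(parent == self.id for parent in self.sub_class_of):
            raise InvariantError(f"class {self.id} lists itself as a parent")
        if not self.label:
            object.__setattr__(self, "label", self.id.local)


@dataclass(frozen=True, slots=True)
class SchemaDocument:
    """One namespace's JSON-LD export: context plus class/property definitions."""

    namespace: str
    context: ContextMap
    classes: tuple[ClassDefinition, ...] = ()
    properties: tuple[PropertyDefinition, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "properties", tuple(self.properties))

    # -- lookups ---------------------------------------------------------

    def get_class(self, class_id: Curie) -> ClassDefinition | None:
        for cls in self.classes:
            if cls.id == class_id:
                return cls
        return None

    def class_ids(self) -> set[Curie]:
        return {cls.id for cls in self.classes}

    def property_ids(self) -> set[Curie]:
        return {prop.id for prop in self.properties}

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check document invariants; raise :class:`InvariantError` on failure."""
        if not self.namespace or self.namespace != self.namespace.lower():
            raise NamespaceError(
                f"namespace must be a lowercase token, got {self.namespace!r}"
            )
        if self.namespace not in self.context:
            raise NamespaceError(
                f"namespace {self.namespace!r} is not bound in the context"
            )
        seen: set[Curie] = set()
        for node in (*self.classes, *self.properties):
            if node.id in seen:
                raise InvariantError(f"duplicate identifier {node.id}")
            seen.add(node.id)
        for curie in self._referenced_curies():
            resolve_curie(self.context, str(curie))

    def _referenced_curies(self):
        for cls in self.classes:
            yield cls.id
            yield from cls.sub_class_of
        for prop in self.properties:
            yield prop.id
            yield from prop.domain_includes
            yield from prop.range_includes

    def with_namespace(self, namespace: str) -> "SchemaDocument":
        return replace(self, namespace=namespace)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _as_id_list(value, where: str) -> tuple[Curie, ...]:
    """Read a subClassOf/domainIncludes/rangeIncludes value: {"@id": c} or list."""
    if value is None:
        return ()
    if isinstance(value, dict):
        value = [value]
    if not isinstance(value, list):
        raise MalformedDocumentError(f"{where}: expected object or list, got {type(value).__name__}")
    out = []
    for entry in value:
        if not isinstance(entry, dict) or "@id" not in entry:
            raise MalformedDocumentError(f'{where}: entries must be {{"@id": ...}} objects')
        out.append(Curie.parse(entry["@id"]))
    return tuple(out)


def _check_naming(kind: str, curie: Curie) -> None:
    pattern = _UPPER_CAMEL_RE if kind == "class" else _LOWER_CAMEL_RE
    style = "UpperCamelCase" if kind == "class" else "lowerCamelCase"
    if not pattern.match(curie.local):
        warnings.warn(
            f"{kind} {curie} does not follow the {style} convention",
            NamingConventionWarning,
            stacklevel=4,
        )


def _parse_class_node(node: dict) -> ClassDefinition:
    from .validation import ValidationRuleSet  # local import: validation depends on us

    curie = Curie.parse(node["@id"])
    _check_naming("class", curie)
    validation = None
    if "$validation" in node:
        validation = ValidationRuleSet.from_dict(node["$validation"])
    return ClassDefinition(
        id=curie,
        label=node.get("rdfs:label", ""),
        description=node.get("rdfs:comment", ""),
        sub_class_of=_as_id_list(node.get("rdfs:subClassOf"), f"class {curie}"),
        validation=validation,
        principal=bool(node.get("x:principal", False)),
    )


def _parse_property_node(node: dict) -> PropertyDefinition:
    curie = Curie.parse(node["@id"])
    _check_naming("property", curie)
    return PropertyDefinition(
        id=curie,
        label=node.get("rdfs:label", ""),
        description=node.get("rdfs:comment", ""),
        domain_includes=_as_id_list(node.get("schema:domainIncludes"), f"property {curie}"),
        range_includes=_as_id_list(node.get("schema:rangeIncludes"), f"property {curie}"),
    )


def _infer_namespace(raw: dict, classes, properties, context: ContextMap) -> str:
    explicit = raw.get("x:namespace")
    if explicit is not None:
        if not isinstance(explicit, str):
            raise NamespaceError("x:namespace must be a string")
        return explicit
    node_prefixes = {n.id.prefix for n in (*classes, *properties)}
    if len(node_prefixes) == 1:
        return next(iter(node_prefixes))
    if len(node_prefixes) > 1:
        raise NamespaceError(
            "document mixes node prefixes "
            f"{sorted(node_prefixes)} but carries no x:namespace annotation"
        )
    candidates = sorted(set(context.prefixes()) - RESERVED_PREFIXES)
    if len(candidates) == 1:
        return candidates[0]
    raise NamespaceError(
        "cannot infer namespace of an empty document: add x:namespace or bind "
        "exactly one non-reserved prefix"
    )


def parse_schema(text: str) -> SchemaDocument:
    """Parse a JSON-LD schema document string into a :class:`SchemaDocument`.

    Nodes typed ``rdfs:Class`` / ``rdf:Property`` become definitions; any other
    node type is reported with :class:`UnknownNodeTypeWarning` rather than
    silently dropped.  Every CURIE in the document must resolve through the
    context or parsing fails with a named error.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedDocumentError(f"not well-formed JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise MalformedDocumentError("top level must be a JSON object")
    if "@context" not in raw:
        raise MissingContextError("document has no @context block")
    if not isinstance(raw["@context"], dict):
        raise MissingContextError("@context must be a prefix->IRI object")
    if "@graph" not in raw or not isinstance(raw["@graph"], list):
        raise MalformedDocumentError("document has no @graph node list")

    context = ContextMap(raw["@context"])
    classes: list[ClassDefinition] = []
    properties: list[PropertyDefinition] = []
    for node in raw["@graph"]:
        if not isinstance(node, dict):
            raise MalformedDocumentError("@graph entries must be objects")
        if "@id" not in node:
            raise NodeIdentifierError(f"node without @id: {json.dumps(node)[:80]}")
        node_type = node.get("@type")
        if node_type == "rdfs:Class":
            classes.append(_parse_class_node(node))
        elif node_type == "rdf:Property":
            properties.append(_parse_property_node(node))
        else:
            warnings.warn(
                f"node {node['@id']} has unknown @type {node_type!r}; ignored",
                UnknownNodeTypeWarning,
                stacklevel=2,
            )

    doc = SchemaDocument(
        namespace=_infer_namespace(raw, classes, properties, context),
        context=context,
        classes=tuple(classes),
        properties=tuple(properties),
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Canonical serialization
# ---------------------------------------------------------------------------

def _id_obj(curie: Curie) -> dict:
    return {"@id": str(curie)}


def _serialize_id_list(curies: tuple[Curie, ...]):
    if len(curies) == 1:
        return _id_obj(curies[0])
    return [_id_obj(c) for c in curies]


def _class_node(cls: ClassDefinition) -> dict:
    node: dict = {"@id": str(cls.id), "@type": "rdfs:Class", "rdfs:label": cls.label}
    if cls.description:
        node["rdfs:comment"] = cls.description
    if cls.sub_class_of:
        node["rdfs:subClassOf"] = _serialize_id_list(cls.sub_class_of)
    if cls.principal:
        node["x:principal"] = True
    if cls.validation is not None:
        node["$validation"] = cls.validation.to_dict()
    return {k: node[k] for k in _NODE_KEY_ORDER if k in node}


def _property_node(prop: PropertyDefinition) -> dict:
    node: dict = {"@id": str(prop.id), "@type": "rdf:Property", "rdfs:label": prop.label}
    if prop.description:
        node["rdfs:comment"] = prop.description
    node["schema:domainIncludes"] = _serialize_id_list(prop.domain_includes)
    if prop.range_includes:
        node["schema:rangeIncludes"] = _serialize_id_list(prop.range_includes)
    return {k: node[k] for k in _NODE_KEY_ORDER if k in node}


def serialize_schema(doc: SchemaDocument) -> str:
    """Canonical JSON-LD text for a document; byte-identical for equal inputs."""
    doc.validate()
    payload = {
        "@context": dict(sorted(doc.context.prefixes().items())),
        "x:namespace": doc.namespace,
        "@graph": [_class_node(c) for c in doc.classes]
        + [_property_node(p) for p in doc.properties],
    }
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
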
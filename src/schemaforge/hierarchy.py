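"""Class-graph construction, ancestor resolution and property inheritance.

Schema.org-style vocabularies form a directed acyclic class graph rooted at
``schema:Thing``; extended classes inherit every property of every ancestor
(``domainIncludes`` membership is unioned down the hierarchy).  Multiple
inheritance is allowed.  Name collisions among inherited properties are
resolved *child-most first, then left-parent first*: precedence is
breadth-first order from the class itself, taking the first occurrence of
each class, which ranks a direct parent ahead of any grandparent and earlier
parents ahead of later ones.

Parents that are named but defined in no loaded document ("dangling") are
tolerated with a warning so users can author against vocabularies they have
not yet imported, but they are dead ends: traversal cannot pass through them
and they never make a class count as rooted in Schema.org.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import (
    CycleError,
    DanglingParentWarning,
    DuplicateDefinitionError,
    UnknownClassError,
)
from .schema_model import ClassDefinition, Curie, SchemaDocument

__all__ = [
    "ClassGraph",
    "EffectiveClassView",
    "build_class_graph",
    "ancestor_chain",
    "ancestors",
    "precedence_order",
    "effective_properties",
    "is_rooted_in_schemaorg",
]


@dataclass(frozen=True, slots=True)
class ClassGraph:
    """Child→parents class graph over one or more schema documents."""

    nodes: frozenset[Curie]
    parents: dict[Curie, tuple[Curie, ...]]
    source: dict[Curie, str]
    dangling: frozenset[Curie]

    def __contains__(self, class_id: Curie) -> bool:
        return class_id in self.nodes

    def require(self, class_id: Curie) -> None:
        if class_id not in self.nodes:
            raise UnknownClassError(f"class {class_id} is not in the graph")

    def parents_of(self, class_id: Curie) -> tuple[Curie, ...]:
        return self.parents.get(class_id, ())

    def to_adjacency(self) -> dict:
        """Machine-readable JSON adjacency (CLI ``view --format json``)."""
        return {
            "nodes": sorted(str(n) for n in self.nodes),
            "edges": {
                str(c): [str(p) for p in ps]
                for c, ps in sorted(self.parents.items(), key=lambda kv: str(kv[0]))
                if ps
            },
            "dangling": sorted(str(d) for d in self.dangling),
            "source": {str(n): ns for n, ns in sorted(self.source.items(), key=lambda kv: str(kv[0]))},
        }


def build_class_graph(docs: Iterable[SchemaDocument]) -> ClassGraph:
    """Build the combined class graph; reject cycles and conflicting duplicates."""
    definitions: dict[Curie, ClassDefinition] = {}
    source: dict[Curie, str] = {}
    for doc in docs:
        for cls in doc.classes:
            if cls.id in definitions:
                if definitions[cls.id] != cls:
                    raise DuplicateDefinitionError(
                        f"class {cls.id} defined differently in {source[cls.id]!r} "
                        f"and {doc.namespace!r}"
                    )
                continue
            definitions[cls.id] = cls
            source[cls.id] = doc.namespace

    parents: dict[Curie, tuple[Curie, ...]] = {}
    dangling: set[Curie] = set()
    nodes: set[Curie] = set(definitions)
    for cid, cls in definitions.items():
        parents[cid] = cls.sub_class_of
        for parent in cls.sub_class_of:
            if parent not in definitions:
                dangling.add(parent)
                nodes.add(parent)
                warnings.warn(
                    f"class {cid} names undefined parent {parent}",
                    DanglingParentWarning,
                    stacklevel=2,
                )

    digraph = nx.DiGraph()
    digraph.add_nodes_from(definitions)
    for cid in definitions:
        for parent in parents[cid]:
            if parent in definitions:
                digraph.add_edge(cid, parent)
    if not nx.is_directed_acyclic_graph(digraph):
        cycle_edges = nx.find_cycle(digraph)
        cycle = [str(edge[0]) for edge in cycle_edges]
        raise CycleError(cycle)

    return ClassGraph(
        nodes=frozenset(nodes),
        parents=parents,
        source=source,
        dangling=frozenset(dangling),
    )


def ancestor_chain(graph: ClassGraph, class_id: Curie) -> list[list[Curie]]:
    """All root-ending ancestor chains of a class, depth-first left-to-right.

    Each chain starts at a direct parent and ends at a parentless class
    (dangling parents are parentless by construction).  A class with no
    parents has no chains: the result is the empty list.
    """
    graph.require(class_id)

    def chains_from(cid: Curie) -> list[list[Curie]]:
        ps = graph.parents_of(cid)
        if not ps:
            return [[]]
        out = []
        for p in ps:
            for tail in chains_from(p):
                out.append([p] + tail)
        return out

    if not graph.parents_of(class_id):
        return []
    return chains_from(class_id)


def ancestors(graph: ClassGraph, class_id: Curie) -> set[Curie]:
    """Set of all (proper) ancestors of a class."""
    return {a for chain in ancestor_chain(graph, class_id) for a in chain}


def precedence_order(graph: ClassGraph, class_id: Curie) -> list[Curie]:
    """Inheritance precedence: self, then BFS over parents, first occurrence.

    This realises the child-most-first, left-parent-first merge rule used by
    both property inheritance and validation compilation.
    """
    graph.require(class_id)
    order: list[Curie] = []
    seen: set[Curie] = set()
    queue = [class_id]
    while queue:
        cid = queue.pop(0)
        if cid in seen:
            continue
        seen.add(cid)
        order.append(cid)
        queue.extend(graph.parents_of(cid))
    return order


@dataclass(frozen=True, slots=True)
class EffectiveClassView:
    """A class with inheritance resolved: ancestors + effective properties."""

    class_id: Curie
    chains: tuple[tuple[Curie, ...], ...]
    properties: dict[str, "object"]  # local name -> PropertyDefinition
    validation: "object | None" = None  # compiled ValidationRuleSet

    def property_names(self) -> set[str]:
        return set(self.properties)


def effective_properties(
    graph: ClassGraph,
    docs: Iterable[SchemaDocument],
    class_id: Curie,
    with_validation: bool = False,
) -> EffectiveClassView:
    """Union of all properties contributed by a class and its ancestors.

    A property contributes to every class named in its ``domainIncludes``.
    Collisions on local name resolve by :func:`precedence_order`; within one
    class, document order wins.
    """
    graph.require(class_id)
    docs = list(docs)
    contributions: dict[Curie, list] = {}
    for doc in docs:
        for prop in doc.properties:
            for domain in prop.domain_includes:
                contributions.setdefault(domain, []).append(prop)

    properties: dict[str, object] = {}
    for cid in precedence_order(graph, class_id):
        for prop in contributions.get(cid, ()):
            if prop.id.local not in properties:
                properties[prop.id.local] = prop

    compiled = None
    if with_validation:
        from .validation import compile_validation

        compiled = compile_validation(graph, docs, class_id)
    return EffectiveClassView(
        class_id=class_id,
        chains=tuple(tuple(c) for c in ancestor_chain(graph, class_id)),
        properties=properties,
        validation=compiled,
    )


def is_rooted_in_schemaorg(graph: ClassGraph, class_id: Curie) -> bool:
    """True iff the class is, or inherits from, a *defined* schema.org class.

    Dangling parents are dead ends: naming an undefined ``schema:`` parent
    does not root a class, since nothing verifiable is known about it.
    """
    graph.require(class_id)

    def is_schema(cid: Curie) -> bool:
        return cid.prefix == "schema" and cid not in graph.dangling

    if is_schema(class_id):
        return True
    return any(is_schema(a) for a in ancestors(graph, class_id))
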
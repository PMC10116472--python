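"""Shared/unique property comparison across two to four classes.

Comparison is over effective (inheritance-inclusive) property *local names*
by default, so ``schema:name`` inherited into an extended class unifies with
the base's ``name``; an ``inherited=False`` flag restricts the comparison to
properties whose domain names the class directly.  Local names carried by
identically-named properties from unrelated namespaces are surfaced in a
footnote list rather than silently unified without comment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .errors import ComparisonLimitError
from .hierarchy import ClassGraph, effective_properties
from .schema_model import Curie, SchemaDocument

__all__ = ["ComparisonResult", "compare_classes", "MAX_COMPARE"]

#: Maximum number of classes that one comparison accepts.
MAX_COMPARE = 4


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    class_ids: tuple[Curie, ...]
    shared: frozenset[str]
    unique: dict[Curie, frozenset[str]]
    pairwise: dict[tuple[Curie, Curie], int]
    #: local names defined by more than one distinct property id across the
    #: compared classes (cross-namespace collisions worth a footnote)
    collisions: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.class_ids],
            "shared": sorted(self.shared),
            "unique": {str(c): sorted(names) for c, names in self.unique.items()},
            "pairwise": {
                f"{a}|{b}": n for (a, b), n in sorted(self.pairwise.items(), key=lambda kv: str(kv[0]))
            },
            "collisions": sorted(self.collisions),
        }


def compare_classes(
    graph: ClassGraph,
    docs: Iterable[SchemaDocument],
    class_ids: list[Curie],
    inherited: bool = True,
) -> ComparisonResult:
    """Partition property names of 2–4 classes into shared and per-class unique."""
    if not 2 <= len(class_ids) <= MAX_COMPARE:
        raise ComparisonLimitError(
            f"comparison accepts 2 to {MAX_COMPARE} classes, got {len(class_ids)}"
        )
    docs = list(docs)
    name_sets: dict[Curie, set[str]] = {}
    prop_ids: dict[str, set[Curie]] = {}
    for cid in class_ids:
        view = effective_properties(graph, docs, cid)
        if not inherited:
            own = {
                name: prop
                for name, prop in view.properties.items()
                if cid in prop.domain_includes
            }
            props = own
        else:
            props = view.properties
        name_sets[cid] = set(props)
        for name, prop in props.items():
            prop_ids.setdefault(name, set()).add(prop.id)

    shared = set.intersection(*(name_sets[c] for c in class_ids))
    unique: dict[Curie, frozenset[str]] = {}
    for c in dict.fromkeys(class_ids):
        others = [name_sets[o] for o in name_sets if o != c]
        unique[c] = frozenset(name_sets[c] - set.union(*others)) if others else frozenset()
    pairwise = {
        (a, b): len(name_sets[a] & name_sets[b])
        for a, b in combinations(dict.fromkeys(class_ids), 2)
    }
    collisions = frozenset(name for name, ids in prop_ids.items() if len(ids) > 1)
    return ComparisonResult(
        class_ids=tuple(class_ids),
        shared=frozenset(shared),
        unique=unique,
        pairwise=pairwise,
        collisions=collisions,
    )
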
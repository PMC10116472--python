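"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from schemaforge import (
    Curie,
    Registry,
    build_class_graph,
    build_outbreak_schema,
    core_vocabulary,
)


@pytest.fixture(scope="session")
def core_doc():
    return core_vocabulary()


@pytest.fixture(scope="session")
def outbreak_doc():
    return build_outbreak_schema()


@pytest.fixture(scope="session")
def all_docs(core_doc, outbreak_doc):
    return [core_doc, outbreak_doc]


@pytest.fixture(scope="session")
def graph(all_docs):
    return build_class_graph(all_docs)


@pytest.fixture()
def store(tmp_path):
    """A fresh registry store (core vocabulary pre-registered)."""
    return Registry(tmp_path / "store")


# ---------------------------------------------------------------------------
# Independent traversal oracles (naive, uncached, recursion-based)
# ---------------------------------------------------------------------------

def doc_parents(docs) -> dict[Curie, tuple[Curie, ...]]:
    """Parent map read straight off the documents, bypassing ClassGraph."""
    parents: dict[Curie, tuple[Curie, ...]] = {}
    for doc in docs:
        for cls in doc.classes:
            parents.setdefault(cls.id, cls.sub_class_of)
    return parents


def oracle_chains(docs, class_id: Curie) -> list[list[Curie]]:
    """Exhaustive enumeration of all root-ending ancestor paths."""
    parents = doc_parents(docs)

    def walk(cid: Curie) -> list[list[Curie]]:
        ps = parents.get(cid, ())
        if not ps:
            return [[]]
        return [[p] + tail for p in ps for tail in walk(p)]

    return [] if not parents.get(class_id, ()) else walk(class_id)


def oracle_precedence(docs, class_id: Curie) -> list[Curie]:
    """Class precedence derived from path enumeration, not BFS.

    Rank every ancestor by (shortest distance, lexicographically smallest
    minimal path of parent indices); the class itself comes first.
    """
    parents = doc_parents(docs)

    def all_paths(cid: Curie, seen=()):  # paths as tuples of (parent index, class)
        yield ()
        for i, p in enumerate(parents.get(cid, ())):
            if p in seen:
                continue
            for tail in all_paths(p, seen + (p,)):
                yield ((i, p),) + tail

    best: dict[Curie, tuple] = {}
    for path in all_paths(class_id):
        for k in range(1, len(path) + 1):
            node = path[k - 1][1]
            key = (k, tuple(step[0] for step in path[:k]))
            if node not in best or key < best[node]:
                best[node] = key
    ordered = sorted(best, key=lambda n: best[n])
    return [class_id] + ordered


def oracle_effective(docs, class_id: Curie) -> dict[str, Curie]:
    """Union-with-override property map via the path-derived precedence."""
    contributions: dict[Curie, list] = {}
    for doc in docs:
        for prop in doc.properties:
            for domain in prop.domain_includes:
                contributions.setdefault(domain, []).append(prop)
    out: dict[str, Curie] = {}
    for cid in oracle_precedence(docs, class_id):
        for prop in contributions.get(cid, ()):
            out.setdefault(prop.id.local, prop.id)
    return out
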
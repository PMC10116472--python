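"""File-backed, searchable schema registry with registration constraints.

Storage layout (no database): a directory holding one canonical ``.jsonld``
file per namespace plus a versioned ``index.json``::

    <store>/
      index.json          {"version": 1, "records": {<ns>: {...}, ...}}
      schema.jsonld       pre-registered read-only core vocabulary
      outbreak.jsonld     ...one file per registered namespace

The registration gate mirrors the registry's constraints on what may be
shared: a document must contain at least one class (classless property-only
vocabularies are refused — their properties can still be *borrowed* by
class-based schemas), at least one class must be rooted in the Schema.org
hierarchy, and the namespace must be fresh (or explicitly overwritten with
``update=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from .errors import NamespaceCollisionError, RegistrationError, RegistryError
from .hierarchy import build_class_graph, is_rooted_in_schemaorg
from .schema_model import SchemaDocument, parse_schema, serialize_schema

__all__ = ["Registry", "RegistryRecord", "INDEX_VERSION"]

INDEX_VERSION = 1


@dataclass(frozen=True, slots=True)
class RegistryRecord:
    namespace: str
    document: SchemaDocument
    registered_at: str
    source: str
    class_index: tuple[tuple[str, str], ...]  # (class id, label)
    readonly: bool = False


class Registry:
    """A schema store rooted at a directory; created on first open.

    The bundled core vocabulary is pre-registered read-only under the
    ``schema`` namespace so every store can resolve Schema.org parents
    without any network access.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self._index_path = self.path / "index.json"
        if not self._index_path.exists():
            self._index = {"version": INDEX_VERSION, "records": {}}
            self._install_core()
        else:
            self._index = json.loads(self._index_path.read_text(encoding="utf-8"))
            if self._index.get("version") != INDEX_VERSION:
                raise RegistryError(
                    f"unsupported index version {self._index.get('version')!r}"
                )

    # -- internals -------------------------------------------------------

    def _install_core(self) -> None:
        from .fixtures import core_vocabulary

        self._write(core_vocabulary(), source="bundled core vocabulary", readonly=True)

    def _write(self, doc: SchemaDocument, source: str, readonly: bool = False) -> RegistryRecord:
        text = serialize_schema(doc)
        filename = f"{doc.namespace}.jsonld"
        (self.path / filename).write_text(text, encoding="utf-8")
        entry = {
            "file": filename,
            "registered_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
            "source": source,
            "classes": [[str(c.id), c.label] for c in doc.classes],
            "readonly": readonly,
        }
        self._index["records"][doc.namespace] = entry
        self._save_index()
        return self._record(doc.namespace, entry, doc)

    def _save_index(self) -> None:
        self._index_path.write_text(
            json.dumps(self._index, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )

    def _record(self, namespace: str, entry: dict, doc: SchemaDocument | None = None) -> RegistryRecord:
        if doc is None:
            doc = parse_schema((self.path / entry["file"]).read_text(encoding="utf-8"))
        return RegistryRecord(
            namespace=namespace,
            document=doc,
            registered_at=entry["registered_at"],
            source=entry["source"],
            class_index=tuple((cid, label) for cid, label in entry["classes"]),
            readonly=entry.get("readonly", False),
        )

    # -- public API ------------------------------------------------------

    def namespaces(self) -> list[str]:
        return sorted(self._index["records"])

    def documents(self) -> list[SchemaDocument]:
        return [self.get(ns).document for ns in self.namespaces()]

    def get(self, namespace: str) -> RegistryRecord:
        entry = self._index["records"].get(namespace)
        if entry is None:
            raise RegistryError(f"namespace {namespace!r} is not registered")
        return self._record(namespace, entry)

    def register(
        self, doc: SchemaDocument, source: str = "", update: bool = False
    ) -> RegistryRecord:
        """Persist a document after the registration gate; store unchanged on failure."""
        doc.validate()
        existing = self._index["records"].get(doc.namespace)
        if existing is not None:
            if existing.get("readonly"):
                raise RegistryError(f"namespace {doc.namespace!r} is read-only")
            if not update:
                raise NamespaceCollisionError(
                    f"namespace {doc.namespace!r} is already registered (use update)"
                )
        if not doc.classes:
            raise RegistrationError(
                "classless metadata vocabularies cannot be registered: "
                "the document defines no class"
            )
        neighbours = [
            self.get(ns).document for ns in self.namespaces() if ns != doc.namespace
        ]
        graph = build_class_graph(neighbours + [doc])
        if not any(is_rooted_in_schemaorg(graph, cls.id) for cls in doc.classes):
            raise RegistrationError(
                f"no class of {doc.namespace!r} is rooted in Schema.org"
            )
        return self._write(doc, source=source)

    def deregister(self, namespace: str) -> bool:
        entry = self._index["records"].get(namespace)
        if entry is None:
            return False
        if entry.get("readonly"):
            raise RegistryError(f"namespace {namespace!r} is read-only")
        (self.path / entry["file"]).unlink(missing_ok=True)
        del self._index["records"][namespace]
        self._save_index()
        return True

    def search(self, query: str, limit: int = 100) -> list[tuple[str, str, str]]:
        """Rank classes by match quality: exact > prefix > substring, then name.

        Matching is case-insensitive over class local names, labels and
        namespaces.  An empty query returns everything (capped at *limit*).
        """
        q = query.strip().casefold()
        hits: list[tuple[int, str, str, str]] = []
        for namespace in self.namespaces():
            entry = self._index["records"][namespace]
            for cid, label in entry["classes"]:
                local = cid.split(":", 1)[1] if ":" in cid else cid
                targets = (local.casefold(), label.casefold(), namespace.casefold())
                if not q:
                    score = 3
                elif any(t == q for t in targets):
                    score = 0
                elif any(t.startswith(q) for t in targets):
                    score = 1
                elif any(q in t for t in targets):
                    score = 2
                else:
                    continue
                hits.append((score, namespace, cid, label))
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        return [(ns, cid, label) for _, ns, cid, label in hits[:limit]]
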
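"""Embedded JSON Schema validation rules: build, compile, apply, exemplify.

Each class in a schema document may embed a *validation rule set*: a restricted
JSON Schema (draft-07 semantics) block that encodes, per property,

* **marginality** — whether the property is required, recommended (absent
  values produce warnings, never invalidity) or optional;
* **cardinality** — whether a property takes one value or many; "many" is
  expressed exactly as ``oneOf[R, {array of R, minItems 1}]`` with no implicit
  scalar-to-list coercion;
* **value constraints** — type/enum/pattern/format checks, including
  ontology-identifier constraints (e.g. restricting ``infectiousAgent`` values
  to NCBI Taxonomy terms given as ``NCBITaxon:<id>`` CURIEs or OBO IRIs).

Only the keyword subset below is accepted; anything else fails loudly at
compile time rather than being silently ignored, so a rule set that
meta-validates here behaves identically under any compliant draft-07
validator (rule sets export to standalone JSON Schema files via
:meth:`ValidationRuleSet.to_json_schema`).

Rule sets compile *down the class hierarchy*: a class's effective rules are
the union over its ancestor chain, required sets accumulate monotonically,
and the child-most definition wins per-property conflicts.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field, replace
from random import Random
from typing import Any, Iterable

from .errors import (
    RuleError,
    UnknownClassError,
    UnknownPropertyError,
    UnsatisfiableRuleError,
    UnsupportedKeywordError,
)
from .schema_model import Curie, SCHEMA_ORG

__all__ = [
    "SUPPORTED_KEYWORDS",
    "ValidationRuleSet",
    "ValidationReport",
    "Violation",
    "check_rule_node",
    "set_marginality",
    "set_cardinality",
    "attach_ontology_constraint",
    "ontology_rule",
    "compile_validation",
    "validate_document",
    "generate_example",
]

SUPPORTED_KEYWORDS = frozenset(
    {
        "type",
        "enum",
        "pattern",
        "format",
        "items",
        "oneOf",
        "anyOf",
        "$ref",
        "description",
        "minItems",
        # object-shape keywords, needed to express ontology-identifier
        # constraints ("object with an identifier matching ...")
        "properties",
        "required",
    }
)

_JSON_TYPES = {
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "object": dict,
    "array": list,
    "null": type(None),
}

_MARGINALITY_LEVELS = ("required", "recommended", "optional")


# ---------------------------------------------------------------------------
# Meta-validation of rule nodes
# ---------------------------------------------------------------------------

def check_rule_node(node: Any, definitions: dict[str, dict], path: str = "") -> None:
    """Verify *node* uses only the supported keyword subset, recursively."""
    if not isinstance(node, dict):
        raise RuleError(f"rule at {path or '<root>'} must be an object, got {type(node).__name__}")
    for key, value in node.items():
        if key not in SUPPORTED_KEYWORDS:
            raise UnsupportedKeywordError(f"unsupported keyword {key!r} at {path or '<root>'}")
        sub = f"{path}/{key}" if path else key
        if key == "type":
            types = value if isinstance(value, list) else [value]
            for t in types:
                if t not in _JSON_TYPES:
                    raise RuleError(f"unknown type {t!r} at {sub}")
        elif key == "enum":
            if not isinstance(value, list) or not value:
                raise UnsatisfiableRuleError(f"enum at {sub} must be a non-empty list")
        elif key == "pattern":
            try:
                re.compile(value)
            except (re.error, TypeError) as exc:
                raise RuleError(f"invalid pattern at {sub}: {exc}") from exc
        elif key == "items":
            check_rule_node(value, definitions, sub)
        elif key in ("oneOf", "anyOf"):
            if not isinstance(value, list) or not value:
                raise UnsatisfiableRuleError(f"{key} at {sub} must be a non-empty list")
            for i, branch in enumerate(value):
                check_rule_node(branch, definitions, f"{sub}[{i}]")
        elif key == "$ref":
            target = _ref_name(value, sub)
            if target not in definitions:
                raise RuleError(f"$ref at {sub} targets missing definition {target!r}")
        elif key == "properties":
            if not isinstance(value, dict):
                raise RuleError(f"properties at {sub} must be an object")
            for name, branch in value.items():
                check_rule_node(branch, definitions, f"{sub}/{name}")
        elif key == "required":
            if not isinstance(value, list) or not all(isinstance(v, str) for v in value):
                raise RuleError(f"required at {sub} must be a list of names")
        elif key == "minItems":
            if not isinstance(value, int) or value < 0:
                raise RuleError(f"minItems at {sub} must be a non-negative integer")


def _ref_name(value: Any, path: str) -> str:
    if not isinstance(value, str) or not value.startswith("#/definitions/"):
        raise RuleError(f"$ref at {path} must look like '#/definitions/<name>'")
    return value[len("#/definitions/"):]


def _canon(node: Any) -> Any:
    """Recursively key-sort a rule node for canonical serialization."""
    if isinstance(node, dict):
        return {k: _canon(node[k]) for k in sorted(node)}
    if isinstance(node, list):
        return [_canon(v) for v in node]
    return node


# ---------------------------------------------------------------------------
# ValidationRuleSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ValidationRuleSet:
    """Per-class validation block: property rules + marginality + definitions.

    Immutable; the editing operations (:func:`set_marginality`,
    :func:`set_cardinality`, :func:`attach_ontology_constraint`) return new
    rule sets and never mutate their input.
    """

    rules: dict[str, dict] = field(default_factory=dict)
    required: tuple[str, ...] = ()
    recommended: tuple[str, ...] = ()
    definitions: dict[str, dict] = field(default_factory=dict)
    class_id: Curie | None = None

    def __post_init__(self):
        object.__setattr__(self, "required", tuple(sorted(set(self.required))))
        object.__setattr__(self, "recommended", tuple(sorted(set(self.recommended))))

    def meta_validate(self) -> None:
        overlap = set(self.required) & set(self.recommended)
        if overlap:
            raise RuleError(f"properties both required and recommended: {sorted(overlap)}")
        for name in (*self.required, *self.recommended):
            if name not in self.rules:
                raise RuleError(f"marginality set for {name!r} but it has no rule")
        for name, node in self.rules.items():
            check_rule_node(node, self.definitions, name)
        for name, node in self.definitions.items():
            check_rule_node(node, self.definitions, f"definitions/{name}")

    def marginality(self, name: str) -> str:
        if name in self.required:
            return "required"
        if name in self.recommended:
            return "recommended"
        return "optional"

    # -- (de)serialization ----------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "ValidationRuleSet":
        if not isinstance(raw, dict):
            raise RuleError("$validation must be an object")
        unknown = set(raw) - {"properties", "required", "recommended", "definitions", "$schema"}
        if unknown:
            raise RuleError(f"unknown $validation keys: {sorted(unknown)}")
        rs = cls(
            rules={k: dict(v) for k, v in raw.get("properties", {}).items()},
            required=tuple(raw.get("required", ())),
            recommended=tuple(raw.get("recommended", ())),
            definitions={k: dict(v) for k, v in raw.get("definitions", {}).items()},
        )
        rs.meta_validate()
        return rs

    def to_dict(self) -> dict:
        out: dict = {}
        if self.definitions:
            out["definitions"] = {k: _canon(self.definitions[k]) for k in sorted(self.definitions)}
        out["properties"] = {k: _canon(self.rules[k]) for k in sorted(self.rules)}
        if self.required:
            out["required"] = list(self.required)
        if self.recommended:
            out["recommended"] = list(self.recommended)
        return out

    def to_json_schema(self) -> dict:
        """Standalone draft-07 document usable by third-party validators."""
        out = {
            "$schema": "http://json-schema.org/draft-07/schema#",
            "type": "object",
            **self.to_dict(),
        }
        return out


# ---------------------------------------------------------------------------
# Rule-set editing operations
# ---------------------------------------------------------------------------

def _require_rule(ruleset: ValidationRuleSet, name: str) -> dict:
    try:
        return ruleset.rules[name]
    except KeyError:
        raise UnknownPropertyError(f"no rule for property {name!r}") from None


def set_marginality(ruleset: ValidationRuleSet, name: str, level: str) -> ValidationRuleSet:
    """Move *name* between the required / recommended / optional levels."""
    if level not in _MARGINALITY_LEVELS:
        raise RuleError(f"marginality must be one of {_MARGINALITY_LEVELS}, got {level!r}")
    _require_rule(ruleset, name)
    required = [n for n in ruleset.required if n != name]
    recommended = [n for n in ruleset.recommended if n != name]
    if level == "required":
        required.append(name)
    elif level == "recommended":
        recommended.append(name)
    return replace(ruleset, required=tuple(required), recommended=tuple(recommended))


def _many_wrapper(rule: dict) -> dict:
    return {"oneOf": [rule, {"type": "array", "items": rule, "minItems": 1}]}


def _unwrap_many(rule: dict) -> tuple[dict, bool]:
    """Return (scalar rule, was_wrapped)."""
    if set(rule) == {"oneOf"} and len(rule["oneOf"]) == 2:
        scalar, arr = rule["oneOf"]
        if arr == {"type": "array", "items": scalar, "minItems": 1}:
            return scalar, True
    return rule, False


def set_cardinality(ruleset: ValidationRuleSet, name: str, arity: str) -> ValidationRuleSet:
    """Allow one value or many for *name*; applying "many" twice is idempotent."""
    if arity not in ("one", "many"):
        raise RuleError(f"cardinality must be 'one' or 'many', got {arity!r}")
    rule = _require_rule(ruleset, name)
    scalar, _ = _unwrap_many(rule)
    new_rule = _many_wrapper(scalar) if arity == "many" else scalar
    rules = dict(ruleset.rules)
    rules[name] = new_rule
    return replace(ruleset, rules=rules)


def ontology_rule(prefix: str, iri_base: str, id_pattern: str = "[A-Za-z0-9_.-]+") -> dict:
    """Rule accepting an object whose ``identifier`` is a term of one ontology.

    The identifier must be either a CURIE ``<prefix>:<id>`` or the full IRI
    ``<iri_base><id>``; e.g. ``NCBITaxon:2697049`` or
    ``http://purl.obolibrary.org/obo/NCBITaxon_2697049``.
    """
    if not prefix:
        raise RuleError("ontology constraint needs a non-empty CURIE prefix")
    if not iri_base:
        raise RuleError("ontology constraint needs a non-empty IRI base")
    return {
        "type": "object",
        "required": ["identifier"],
        "properties": {
            "identifier": {
                "anyOf": [
                    {"type": "string", "pattern": f"^{re.escape(prefix)}:{id_pattern}$"},
                    {"type": "string", "pattern": f"^{re.escape(iri_base)}{id_pattern}$"},
                ]
            },
            "name": {"type": "string"},
        },
    }


def attach_ontology_constraint(
    ruleset: ValidationRuleSet, name: str, ontology: dict
) -> ValidationRuleSet:
    """Constrain *name* to values standardized by an ontology.

    *ontology* is ``{"prefix": ..., "iri_base": ..., "id_pattern": ...}``
    (id_pattern optional, defaults to a generic token pattern; use ``[0-9]+``
    for purely numeric ontologies such as NCBI Taxonomy).
    """
    _require_rule(ruleset, name)
    if not ontology or not isinstance(ontology, dict):
        raise RuleError("empty ontology spec")
    rule = ontology_rule(
        ontology.get("prefix", ""),
        ontology.get("iri_base", ""),
        ontology.get("id_pattern", "[A-Za-z0-9_.-]+"),
    )
    rules = dict(ruleset.rules)
    rules[name] = rule
    return replace(ruleset, rules=rules)


# ---------------------------------------------------------------------------
# Compilation down the class hierarchy
# ---------------------------------------------------------------------------

def compile_validation(graph, docs, class_id: Curie) -> ValidationRuleSet:
    """Effective rule set of *class_id*: union over its ancestor chain.

    Required and recommended sets accumulate (required wins when both name the
    same property); per-property rule conflicts resolve child-most first, then
    left-parent-first.  The result meta-validates and every referenced name is
    checked against the class's effective property set.
    """
    from .hierarchy import effective_properties, precedence_order

    order = precedence_order(graph, class_id)  # child-most first
    doc_index = {}
    for doc in docs:
        for cls in doc.classes:
            doc_index.setdefault(cls.id, cls)

    rules: dict[str, dict] = {}
    definitions: dict[str, dict] = {}
    required: set[str] = set()
    recommended: set[str] = set()
    # walk ancestor-most -> child-most so later (childer) updates win
    for cid in reversed(order):
        cls = doc_index.get(cid)
        if cls is None or cls.validation is None:
            continue
        rs: ValidationRuleSet = cls.validation
        rules.update(rs.rules)
        definitions.update(rs.definitions)
        required.update(rs.required)
        recommended.update(rs.recommended)
    recommended -= required

    view = effective_properties(graph, docs, class_id)
    effective_names = set(view.properties)
    stray = set(rules) - effective_names
    if stray:
        raise RuleError(
            f"rules reference properties outside the effective set of {class_id}: {sorted(stray)}"
        )
    compiled = ValidationRuleSet(
        rules=rules,
        required=tuple(sorted(required)),
        recommended=tuple(sorted(recommended)),
        definitions=definitions,
        class_id=class_id,
    )
    compiled.meta_validate()
    return compiled


# ---------------------------------------------------------------------------
# Instance validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class Violation:
    path: str
    keyword: str
    message: str


@dataclass(frozen=True, slots=True)
class ValidationReport:
    violations: tuple[Violation, ...]
    warnings: tuple[tuple[str, str], ...]

    @property
    def valid(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        status = "VALID" if self.valid else "INVALID"
        lines = [status]
        for v in self.violations:
            lines.append(f"  violation at {v.path} [{v.keyword}]: {v.message}")
        for path, msg in self.warnings:
            lines.append(f"  warning at {path}: {msg}")
        return "\n".join(lines)


def _deref(rule: dict, definitions: dict[str, dict]) -> dict:
    while "$ref" in rule:
        rule = definitions[_ref_name(rule["$ref"], "$ref")]
    return rule


_FORMAT_RES = {
    "uri": re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S+$"),
    "date": re.compile(r"^\d{4}-\d{2}-\d{2}$"),
    "date-time": re.compile(r"^\d{4}-\d{2}-\d{2}[Tt ]\d{2}:\d{2}:\d{2}"),
    "email": re.compile(r"^[^@\s]+@[^@\s]+\.[^@\s]+$"),
}


def _check_type(value: Any, type_names: list[str]) -> bool:
    for t in type_names:
        py = _JSON_TYPES[t]
        if t in ("integer", "number") and isinstance(value, bool):
            continue
        if isinstance(value, py):
            return True
    return False


def _validate_node(
    value: Any, rule: dict, definitions: dict[str, dict], path: str
) -> list[Violation]:
    rule = _deref(rule, definitions)
    out: list[Violation] = []
    if "type" in rule:
        types = rule["type"] if isinstance(rule["type"], list) else [rule["type"]]
        if not _check_type(value, types):
            out.append(
                Violation(path, "type", f"expected {' or '.join(types)}, got {type(value).__name__}")
            )
            return out  # further keyword checks would be noise
    if "enum" in rule and value not in rule["enum"]:
        out.append(Violation(path, "enum", f"{value!r} not one of {rule['enum']!r}"))
    if "pattern" in rule and isinstance(value, str):
        if not re.search(rule["pattern"], value):
            out.append(Violation(path, "pattern", f"{value!r} does not match {rule['pattern']!r}"))
    if "format" in rule and isinstance(value, str):
        fmt = _FORMAT_RES.get(rule["format"])
        if fmt is not None and not fmt.match(value):
            out.append(Violation(path, "format", f"{value!r} is not a valid {rule['format']}"))
    if isinstance(value, list):
        if "minItems" in rule and len(value) < rule["minItems"]:
            out.append(Violation(path, "minItems", f"needs >= {rule['minItems']} items"))
        if "items" in rule:
            for i, item in enumerate(value):
                out.extend(_validate_node(item, rule["items"], definitions, f"{path}[{i}]"))
    if isinstance(value, dict):
        for req in rule.get("required", ()):
            if req not in value:
                out.append(Violation(f"{path}.{req}", "required", f"missing required key {req!r}"))
        for name, sub in rule.get("properties", {}).items():
            if name in value:
                out.extend(_validate_node(value[name], sub, definitions, f"{path}.{name}"))
    if "oneOf" in rule:
        matches = sum(
            1 for branch in rule["oneOf"] if not _validate_node(value, branch, definitions, path)
        )
        if matches != 1:
            out.append(Violation(path, "oneOf", f"matched {matches} of {len(rule['oneOf'])} branches"))
    if "anyOf" in rule:
        if all(_validate_node(value, branch, definitions, path) for branch in rule["anyOf"]):
            out.append(Violation(path, "anyOf", "no branch matched"))
    return out


def validate_document(instance: Any, compiled: ValidationRuleSet) -> ValidationReport:
    """Check one JSON metadata instance against a compiled rule set.

    Violations (wrong ``@type``, missing required properties, value-rule
    breaches) make the instance invalid; missing *recommended* properties and
    unknown non-``@`` properties only produce warnings.
    """
    if not isinstance(instance, dict):
        raise TypeError("instance must be a JSON object")
    violations: list[Violation] = []
    warnings_: list[tuple[str, str]] = []

    if compiled.class_id is not None:
        declared = instance.get("@type")
        expected = str(compiled.class_id)
        if declared != expected:
            violations.append(
                Violation("@type", "const", f"expected {expected!r}, got {declared!r}")
            )

    for name in compiled.required:
        if name not in instance:
            violations.append(Violation(name, "required", f"missing required property {name!r}"))
    for name in compiled.recommended:
        if name not in instance:
            warnings_.append((name, f"recommended property {name!r} is absent"))

    for name, value in instance.items():
        if name.startswith("@"):
            continue
        rule = compiled.rules.get(name)
        if rule is None:
            warnings_.append((name, f"property {name!r} has no rule in this class"))
            continue
        violations.extend(_validate_node(value, rule, compiled.definitions, name))

    return ValidationReport(violations=tuple(violations), warnings=tuple(warnings_))


# ---------------------------------------------------------------------------
# Example-markup generation
# ---------------------------------------------------------------------------

_WORDS = (
    "alpha", "beta", "gamma", "delta", "omicron", "sierra", "tango",
    "metadata", "sample", "assay", "cohort", "sequence", "variant",
)


def _sample_pattern(pattern: str, rng: Random) -> str:
    """Draw a string matching *pattern* by walking the compiled regex tree."""
    try:
        import re._parser as sre_parse  # Python >= 3.11
    except ImportError:  # pragma: no cover - older interpreters
        import sre_parse

    def emit(tree) -> str:
        parts = []
        for op, arg in tree:
            opname = str(op)
            if opname == "LITERAL":
                parts.append(chr(arg))
            elif opname == "NOT_LITERAL":
                ch = "a" if chr(arg) != "a" else "b"
                parts.append(ch)
            elif opname == "ANY":
                parts.append(rng.choice(string.ascii_lowercase))
            elif opname == "IN":
                parts.append(pick_in(arg))
            elif opname in ("MAX_REPEAT", "MIN_REPEAT"):
                lo, hi, sub = arg
                hi = lo + 2 if hi > lo + 2 else hi
                n = rng.randint(max(lo, 1 if lo == 0 and hi > 0 else lo), max(lo, min(hi, lo + 2)))
                parts.append("".join(emit(sub) for _ in range(n)))
            elif opname == "SUBPATTERN":
                parts.append(emit(arg[3]))
            elif opname == "BRANCH":
                parts.append(emit(rng.choice(arg[1])))
            elif opname == "AT":
                pass  # anchors contribute nothing
            elif opname == "CATEGORY":  # pragma: no cover - reached via IN
                parts.append(pick_category(arg))
            else:
                raise UnsatisfiableRuleError(f"cannot sample regex construct {opname} in {pattern!r}")
        return "".join(parts)

    def pick_category(arg) -> str:
        name = str(arg)
        if "DIGIT" in name and "NOT" not in name:
            return rng.choice(string.digits)
        if "WORD" in name and "NOT" not in name:
            return rng.choice(string.ascii_lowercase)
        if "SPACE" in name and "NOT" not in name:
            return " "
        return rng.choice(string.ascii_lowercase)

    def pick_in(items) -> str:
        choices: list[str] = []
        for op, arg in items:
            opname = str(op)
            if opname == "LITERAL":
                choices.append(chr(arg))
            elif opname == "RANGE":
                lo, hi = arg
                choices.append(chr(rng.randint(lo, min(hi, lo + 25))))
            elif opname == "CATEGORY":
                choices.append(pick_category(arg))
            elif opname == "NEGATE":
                return rng.choice(string.ascii_lowercase)
        if not choices:
            raise UnsatisfiableRuleError(f"empty character class in {pattern!r}")
        return rng.choice(choices)

    candidate = emit(sre_parse.parse(pattern))
    if not re.search(pattern, candidate):  # pragma: no cover - safety net
        raise UnsatisfiableRuleError(f"failed to synthesize a match for {pattern!r}")
    return candidate


def _generate_value(rule: dict, definitions: dict[str, dict], rng: Random) -> Any:
    rule = _deref(rule, definitions)
    if "enum" in rule:
        if not rule["enum"]:
            raise UnsatisfiableRuleError("empty enum")
        return rng.choice(rule["enum"])
    if "oneOf" in rule:
        return _generate_value(rule["oneOf"][0], definitions, rng)
    if "anyOf" in rule:
        return _generate_value(rng.choice(rule["anyOf"]), definitions, rng)

    types = rule.get("type", "string")
    t = types[0] if isinstance(types, list) else types
    if t == "string":
        if "pattern" in rule:
            return _sample_pattern(rule["pattern"], rng)
        fmt = rule.get("format")
        if fmt == "uri":
            return f"https://example.org/resource/{rng.randint(1, 9999)}"
        if fmt == "date":
            return f"20{rng.randint(10, 29)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
        if fmt == "date-time":
            return (
                f"20{rng.randint(10, 29)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
                f"T{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}:{rng.randint(0, 59):02d}Z"
            )
        if fmt == "email":
            return f"{rng.choice(_WORDS)}@example.org"
        return " ".join(rng.choice(_WORDS) for _ in range(rng.randint(1, 3)))
    if t == "integer":
        return rng.randint(0, 1000)
    if t == "number":
        return round(rng.uniform(0, 100), 3)
    if t == "boolean":
        return rng.random() < 0.5
    if t == "null":
        return None
    if t == "array":
        items = rule.get("items", {"type": "string"})
        n = max(rule.get("minItems", 1), 1)
        return [_generate_value(items, definitions, rng) for _ in range(n)]
    if t == "object":
        out = {}
        props = rule.get("properties", {})
        for name in rule.get("required", ()):
            out[name] = _generate_value(props.get(name, {"type": "string"}), definitions, rng)
        return out
    raise UnsatisfiableRuleError(f"cannot generate a value for rule {rule!r}")


def generate_example(
    compiled: ValidationRuleSet,
    class_id: Curie,
    seed: int,
    context: dict[str, str] | None = None,
) -> dict:
    """Deterministic example markup for a class: every required property is
    present with a value satisfying its rule, so the output always validates.
    """
    compiled.meta_validate()
    rng = Random(seed)
    out: dict[str, Any] = {
        "@context": dict(sorted((context or {"schema": SCHEMA_ORG}).items())),
        "@type": str(class_id),
    }
    for name in compiled.required:
        out[name] = _generate_value(compiled.rules[name], compiled.definitions, rng)
    return out
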
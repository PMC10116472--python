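"""Bundled vocabularies and generators: the offline test bed.

Three kinds of input replace all network access:

* :func:`core_vocabulary` — a miniature, curated snapshot of the Schema.org
  class hierarchy (16 classes rooted at ``schema:Thing``, a handful of
  properties each).  It is a *fixture-scope* snapshot, not a fidelity claim:
  real Schema.org classes carry many more properties, and some intermediate
  classes (``MediaObject``, ``Grant``, ``Article``) are flattened out of the
  parent chains.
* :func:`build_outbreak_schema` — the 22-class COVID-19 Outbreak schema:
  six principal resource types (Analysis, Dataset, ClinicalTrial,
  ComputationalTool, Protocol, Publication) extended from Schema.org classes,
  plus support classes wired in through lowerCamelCase linking properties
  (e.g. ``ClinicalTrial.armGroup`` ranges over ``outbreak:ArmGroup``).  The
  Dataset class carries an ``infectiousAgent`` property constrained to NCBI
  Taxonomy identifiers.
* :func:`random_schema` / :func:`sample_documents` — seeded random schemas
  (always acyclic, optionally rooted in the core snapshot) and labeled
  valid/invalid metadata instances, each invalid instance carrying exactly
  one named, generator-guaranteed defect.
"""

from __future__ import annotations

from dataclasses import dataclass
from random import Random
from typing import Iterable

from .errors import UnsatisfiableRuleError
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
    _generate_value,
    _unwrap_many,
    generate_example,
    ontology_rule,
)

__all__ = [
    "core_vocabulary",
    "build_outbreak_schema",
    "random_schema",
    "sample_documents",
    "LabeledInstance",
    "OUTBREAK_CLASS_PARENTS",
    "OUTBREAK_PRINCIPAL_CLASSES",
    "NCBI_TAXON",
]

#: NCBI Taxonomy ontology constraint spec (identifier per term: digits).
NCBI_TAXON = {
    "prefix": "NCBITaxon",
    "iri_base": "http://purl.obolibrary.org/obo/NCBITaxon_",
    "id_pattern": "[0-9]+",
}


def _c(token: str) -> Curie:
    return Curie.parse(token)


# ---------------------------------------------------------------------------
# Core Schema.org snapshot
# ---------------------------------------------------------------------------

# class -> parent (None = root); chains are flattened where the snapshot
# omits intermediate Schema.org classes.
_CORE_CLASSES: dict[str, str | None] = {
    "Thing": None,
    "CreativeWork": "Thing",
    "Dataset": "CreativeWork",
    "DataDownload": "CreativeWork",
    "MedicalEntity": "Thing",
    "MedicalStudy": "MedicalEntity",
    "MedicalTrial": "MedicalStudy",
    "MedicalObservationalStudy": "MedicalStudy",
    "MedicalScholarlyArticle": "CreativeWork",
    "HowTo": "CreativeWork",
    "SoftwareApplication": "CreativeWork",
    "Person": "Thing",
    "Organization": "Thing",
    "MonetaryGrant": "Thing",
    "Product": "Thing",
    "Place": "Thing",
}

# property -> (domain class, ranges)
_CORE_PROPERTIES: dict[str, tuple[str, tuple[str, ...]]] = {
    "name": ("Thing", ("Text",)),
    "description": ("Thing", ("Text",)),
    "identifier": ("Thing", ("Text", "URL")),
    "url": ("Thing", ("URL",)),
    "alternateName": ("Thing", ("Text",)),
    "author": ("CreativeWork", ("Person", "Organization")),
    "datePublished": ("CreativeWork", ("Date",)),
    "license": ("CreativeWork", ("URL", "Text")),
    "citation": ("CreativeWork", ("CreativeWork", "Text")),
    "keywords": ("CreativeWork", ("Text",)),
    "distribution": ("Dataset", ("DataDownload",)),
    "measurementTechnique": ("Dataset", ("Text", "URL")),
    "variableMeasured": ("Dataset", ("Text",)),
    "temporalCoverage": ("Dataset", ("Text",)),
    "spatialCoverage": ("Dataset", ("Place", "Text")),
    "contentUrl": ("DataDownload", ("URL",)),
    "encodingFormat": ("DataDownload", ("Text",)),
    "contentSize": ("DataDownload", ("Text",)),
    "code": ("MedicalEntity", ("Text",)),
    "legalStatus": ("MedicalEntity", ("Text",)),
    "healthCondition": ("MedicalStudy", ("Text",)),
    "sponsor": ("MedicalStudy", ("Organization", "Person")),
    "status": ("MedicalStudy", ("Text",)),
    "studySubject": ("MedicalStudy", ("Text",)),
    "studyLocation": ("MedicalStudy", ("Place",)),
    "trialDesign": ("MedicalTrial", ("Text",)),
    "studyDesign": ("MedicalObservationalStudy", ("Text",)),
    "publicationType": ("MedicalScholarlyArticle", ("Text",)),
    "pagination": ("MedicalScholarlyArticle", ("Text",)),
    "step": ("HowTo", ("Text",)),
    "tool": ("HowTo", ("Text", "Product")),
    "supply": ("HowTo", ("Text", "Product")),
    "estimatedCost": ("HowTo", ("Text",)),
    "applicationCategory": ("SoftwareApplication", ("Text",)),
    "operatingSystem": ("SoftwareApplication", ("Text",)),
    "softwareVersion": ("SoftwareApplication", ("Text",)),
    "downloadUrl": ("SoftwareApplication", ("URL",)),
    "featureList": ("SoftwareApplication", ("Text",)),
    "givenName": ("Person", ("Text",)),
    "familyName": ("Person", ("Text",)),
    "affiliation": ("Person", ("Organization",)),
    "email": ("Person", ("Text",)),
    "legalName": ("Organization", ("Text",)),
    "parentOrganization": ("Organization", ("Organization",)),
    "funder": ("MonetaryGrant", ("Organization", "Person")),
    "amount": ("MonetaryGrant", ("Number",)),
    "manufacturer": ("Product", ("Organization",)),
    "productID": ("Product", ("Text",)),
    "address": ("Place", ("Text",)),
    "geo": ("Place", ("Text",)),
}


def core_vocabulary() -> SchemaDocument:
    """Deterministic snapshot of the Schema.org classes the fixtures need."""
    context = ContextMap(DEFAULT_PREFIXES)
    classes = tuple(
        ClassDefinition(
            id=_c(f"schema:{name}"),
            label=name,
            description=f"Schema.org {name} class (curated snapshot).",
            sub_class_of=(_c(f"schema:{parent}"),) if parent else (),
        )
        for name, parent in _CORE_CLASSES.items()
    )
    properties = tuple(
        PropertyDefinition(
            id=_c(f"schema:{name}"),
            label=name,
            description=f"Schema.org {name} property (curated snapshot).",
            domain_includes=(_c(f"schema:{domain}"),),
            range_includes=tuple(_c(f"schema:{r}") for r in ranges),
        )
        for name, (domain, ranges) in _CORE_PROPERTIES.items()
    )
    doc = SchemaDocument(
        namespace="schema", context=context, classes=classes, properties=properties
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# COVID-19 Outbreak schema
# ---------------------------------------------------------------------------

#: class -> (source Schema.org class, provenance note)
OUTBREAK_CLASS_PARENTS: dict[str, tuple[str, str]] = {
    "Analysis": ("CreativeWork", "Inspired by Outbreak Protocol, Dataset class, various COVID-19 analyses."),
    "ClinicalTrial": ("MedicalStudy", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "ComputationalTool": ("SoftwareApplication", "Inspired by Bioschemas, NIAID schema, Bio.tools schema."),
    "DataDownload": ("DataDownload", "Inspired by NIAID schema."),
    "Dataset": ("Dataset", "Inspired by NIAID schema."),
    "Protocol": ("HowTo", "Inspired by Bioschemas LabProtocol, protocols.io."),
    "Publication": ("MedicalScholarlyArticle", "Inspired by NLM Medline, biorxiv, various journals."),
    "ArmGroup": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "CitationObject": ("CreativeWork", "Inspired by Outbreak primary classes."),
    "Correction": ("CreativeWork", "Inspired by CitationObject."),
    "Eligibility": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "Instrument": ("Product", "Inspired by Bioschemas LabProtocol, protocols.io."),
    "Intervention": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "MonetaryGrant": ("MonetaryGrant", "Inspired by NIAID schema."),
    "Organization": ("Organization", "Inspired by NIAID schema."),
    "Outcome": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "Person": ("Person", "Inspired by NIAID schema."),
    "Product": ("Product", "Inspired by Bioschemas LabProtocol, protocols.io."),
    "StudyEvent": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "StudyStatus": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "StudyDesign": ("Thing", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
    "StudyLocation": ("Place", "Inspired by NCT Clinical Trials PRS, WHO ClinicalTrials."),
}

OUTBREAK_PRINCIPAL_CLASSES = (
    "Analysis",
    "Dataset",
    "ClinicalTrial",
    "ComputationalTool",
    "Protocol",
    "Publication",
)

_ALL_PRINCIPAL = tuple(f"outbreak:{n}" for n in OUTBREAK_PRINCIPAL_CLASSES)

#: support class -> classes its linking property belongs to ("used in")
_OUTBREAK_LINKS: dict[str, tuple[str, ...]] = {
    "ArmGroup": ("outbreak:ClinicalTrial",),
    "CitationObject": _ALL_PRINCIPAL,
    "Correction": ("outbreak:Publication",),
    "DataDownload": ("outbreak:ComputationalTool", "outbreak:Dataset"),
    "Eligibility": ("outbreak:ClinicalTrial",),
    "Instrument": ("outbreak:Protocol",),
    "Intervention": ("outbreak:ClinicalTrial",),
    "MonetaryGrant": _ALL_PRINCIPAL,
    "Organization": _ALL_PRINCIPAL,
    "Outcome": ("outbreak:ClinicalTrial",),
    "Person": _ALL_PRINCIPAL,
    "Product": ("outbreak:Protocol",),
    "StudyEvent": ("outbreak:ClinicalTrial",),
    "StudyStatus": ("outbreak:ClinicalTrial",),
    "StudyDesign": ("outbreak:ClinicalTrial",),
    "StudyLocation": ("outbreak:ClinicalTrial",),
}


def _lower_camel(name: str) -> str:
    return name[0].lower() + name[1:]


def _outbreak_validation() -> dict[str, ValidationRuleSet]:
    """Embedded validation blocks for the principal Outbreak classes."""
    string = {"type": "string"}
    many_string = {"oneOf": [string, {"type": "array", "items": string, "minItems": 1}]}
    return {
        "Dataset": ValidationRuleSet(
            rules={
                "name": dict(string),
                "description": dict(string),
                "identifier": dict(string),
                "url": {"type": "string", "format": "uri"},
                "citation": dict(many_string),
                "infectiousAgent": ontology_rule(**NCBI_TAXON),
            },
            required=("name", "description", "infectiousAgent"),
            recommended=("identifier", "url"),
        ),
        "ClinicalTrial": ValidationRuleSet(
            rules={
                "name": dict(string),
                "healthCondition": dict(many_string),
                "armGroup": {"type": "object"},
            },
            required=("name",),
            recommended=("healthCondition",),
        ),
        "Protocol": ValidationRuleSet(
            rules={"name": dict(string), "tool": dict(many_string)},
            required=("name",),
            recommended=("tool",),
        ),
        "Publication": ValidationRuleSet(
            rules={
                "name": dict(string),
                "datePublished": {"type": "string", "format": "date"},
                "author": {
                    "oneOf": [
                        {"$ref": "#/definitions/person"},
                        {"type": "array", "items": {"$ref": "#/definitions/person"}, "minItems": 1},
                    ]
                },
            },
            required=("name",),
            recommended=("datePublished", "author"),
            definitions={
                "person": {
                    "type": "object",
                    "required": ["name"],
                    "properties": {"name": {"type": "string"}},
                }
            },
        ),
    }


def build_outbreak_schema() -> SchemaDocument:
    """The merged, multi-class COVID-19 Outbreak schema (22 classes)."""
    context = ContextMap(DEFAULT_PREFIXES)
    context.bind("outbreak", namespace_iri("outbreak"))
    validation = _outbreak_validation()

    classes = tuple(
        ClassDefinition(
            id=_c(f"outbreak:{name}"),
            label=name,
            description=f"Outbreak {name} class. {note}",
            sub_class_of=(_c(f"schema:{source}"),),
            validation=validation.get(name),
            principal=name in OUTBREAK_PRINCIPAL_CLASSES,
        )
        for name, (source, note) in OUTBREAK_CLASS_PARENTS.items()
    )

    properties = [
        PropertyDefinition(
            id=_c("outbreak:infectiousAgent"),
            label="infectiousAgent",
            description=(
                "Pathogen the resource concerns, standardized to the NCBI "
                "Taxonomy ontology (e.g. NCBITaxon:2697049 for SARS-CoV-2)."
            ),
            domain_includes=(_c("outbreak:Dataset"),),
            range_includes=(_c("schema:Thing"),),
        )
    ]
    for support, domains in _OUTBREAK_LINKS.items():
        properties.append(
            PropertyDefinition(
                id=_c(f"outbreak:{_lower_camel(support)}"),
                label=_lower_camel(support),
                description=f"Link to the supporting {support} class.",
                domain_includes=tuple(_c(d) for d in domains),
                range_includes=(_c(f"outbreak:{support}"),),
            )
        )

    doc = SchemaDocument(
        namespace="outbreak",
        context=context,
        classes=classes,
        properties=tuple(properties),
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Random schema / corpus generators
# ---------------------------------------------------------------------------

_RULE_MENU: tuple[dict, ...] = (
    {"type": "string"},
    {"type": "integer"},
    {"type": "number"},
    {"type": "boolean"},
    {"type": "string", "pattern": "^[a-z]{3,8}$"},
    {"enum": ["alpha", "beta", "gamma"], "type": "string"},
    {"type": "array", "items": {"type": "string"}, "minItems": 1},
    {
        "type": "object",
        "required": ["name"],
        "properties": {"name": {"type": "string"}},
    },
    ontology_rule("XONT", "https://example.org/xont/", "[0-9]+"),
)


def random_schema(
    seed: int,
    n_classes: int = 6,
    n_props: int = 10,
    namespace: str | None = None,
    rooted: bool = True,
) -> SchemaDocument:
    """Seeded random schema document that always graph-builds (acyclic).

    Classes may multiply inherit from earlier classes only; when *rooted*,
    the first class subclasses ``schema:Thing`` so the document passes the
    registration gate once the core vocabulary is loaded.
    """
    if n_classes < 1:
        raise UnsatisfiableRuleError("need at least one class")
    rng = Random(seed)
    ns = namespace or f"rnd{seed % 100000}"
    context = ContextMap(DEFAULT_PREFIXES)
    context.bind(ns, namespace_iri(ns))

    class_names = [f"RandomClass{i}" for i in range(n_classes)]
    prop_names = [f"randomProp{i}" for i in range(n_props)]

    # properties first, so validation rules can reference own properties
    prop_domains: dict[str, list[str]] = {name: [] for name in class_names}
    properties = []
    for i, pname in enumerate(prop_names):
        owner = rng.choice(class_names)
        prop_domains[owner].append(pname)
        properties.append(
            PropertyDefinition(
                id=_c(f"{ns}:{pname}"),
                domain_includes=(_c(f"{ns}:{owner}"),),
                range_includes=(_c("schema:Text"),),
            )
        )

    classes = []
    for i, cname in enumerate(class_names):
        if i == 0:
            parents = (_c("schema:Thing"),) if rooted else ()
        else:
            k = rng.randint(1, min(2, i))
            picks = rng.sample(class_names[:i], k)
            parents = tuple(_c(f"{ns}:{p}") for p in picks)
        ruleset = None
        own = prop_domains[cname]
        if own and rng.random() < 0.7:
            rules = {}
            required, recommended = [], []
            for pname in own:
                rules[pname] = dict(rng.choice(_RULE_MENU))
                roll = rng.random()
                if roll < 0.5:
                    required.append(pname)
                elif roll < 0.75:
                    recommended.append(pname)
            ruleset = ValidationRuleSet(
                rules=rules, required=tuple(required), recommended=tuple(recommended)
            )
        classes.append(
            ClassDefinition(
                id=_c(f"{ns}:{cname}"),
                sub_class_of=parents,
                validation=ruleset,
                principal=(i == 0),
            )
        )

    doc = SchemaDocument(
        namespace=ns, context=context, classes=tuple(classes), properties=tuple(properties)
    )
    doc.validate()
    return doc


@dataclass(frozen=True, slots=True)
class LabeledInstance:
    """A metadata instance with generator-embedded ground truth."""

    instance: dict
    valid: bool
    defect: str | None  # None when valid


_BAD_BY_TYPE = {
    "string": 12345,
    "integer": "twelve",
    "number": "pi",
    "boolean": "yes",
    "object": "free text, not an object",
    "array": "scalar, not an array",
    "null": "x",
}


def _is_ontology_rule(rule: dict) -> bool:
    ident = rule.get("properties", {}).get("identifier", {})
    return "identifier" in rule.get("required", ()) and "anyOf" in ident


def _applicable_defects(compiled: ValidationRuleSet) -> dict[str, list[str]]:
    """Map defect kind -> property names it can be injected into."""
    out: dict[str, list[str]] = {
        "missing_required": list(compiled.required),
        "wrong_type": [],
        "cardinality_breach": [],
        "ontology_breach": [],
    }
    for name, rule in compiled.rules.items():
        scalar, wrapped = _unwrap_many(rule)
        if "$ref" in scalar:
            scalar = compiled.definitions.get(scalar["$ref"].rsplit("/", 1)[-1], {})
        if "type" in scalar and isinstance(scalar["type"], str):
            out["wrong_type"].append(name)
            if scalar["type"] not in ("array",):
                out["cardinality_breach"].append(name)
        if _is_ontology_rule(scalar):
            out["ontology_breach"].append(name)
    return {k: v for k, v in out.items() if v}


def sample_documents(
    compiled: ValidationRuleSet,
    n: int,
    invalid_fraction: float,
    seed: int,
) -> list[LabeledInstance]:
    """Seeded corpus of labeled instances for one compiled class.

    Valid instances come straight from :func:`generate_example`.  Invalid
    ones start from a valid instance and receive exactly one named defect
    whose effect on validity is guaranteed by construction: a deleted
    required key, a value of the wrong JSON type, a cardinality breach
    (empty or unexpected array), or an ontology-identifier pattern breach.
    """
    if not 0 <= invalid_fraction <= 1:
        raise ValueError("invalid_fraction must be within [0, 1]")
    rng = Random(seed)
    n_invalid = round(n * invalid_fraction)
    defects = _applicable_defects(compiled)
    if n_invalid and not defects:
        raise UnsatisfiableRuleError(
            "rule set offers no property into which a defect can be injected"
        )
    corpus: list[LabeledInstance] = []
    for i in range(n):
        instance = generate_example(compiled, compiled.class_id, seed=rng.getrandbits(30))
        if i >= n - n_invalid:
            kind = rng.choice(sorted(defects))
            name = rng.choice(defects[kind])
            if kind == "missing_required":
                del instance[name]
            elif kind == "wrong_type":
                scalar, _ = _unwrap_many(compiled.rules[name])
                if "$ref" in scalar:
                    scalar = compiled.definitions[scalar["$ref"].rsplit("/", 1)[-1]]
                instance[name] = _BAD_BY_TYPE[scalar["type"]]
            elif kind == "cardinality_breach":
                scalar, wrapped = _unwrap_many(compiled.rules[name])
                if wrapped:
                    instance[name] = []
                else:
                    value = instance.get(name)
                    if value is None:
                        value = _generate_value(scalar, compiled.definitions, rng)
                    instance[name] = [value, value]
            else:  # ontology_breach
                instance[name] = {"identifier": "%% not an ontology term %%"}
            corpus.append(LabeledInstance(instance=instance, valid=False, defect=kind))
        else:
            corpus.append(LabeledInstance(instance=instance, valid=True, defect=None))
    return corpus
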
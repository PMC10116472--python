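# schemaforge

Offline tooling for **class-based biomedical metadata schemas**: author,
extend, validate, compare and register Schema.org-style vocabularies
expressed as JSON-LD with embedded JSON Schema validation rules.

Biomedical resource providers who want their datasets, protocols, trials or
tools to be FAIR (Findable, Accessible, Interoperable, Reusable) typically
start from a Schema.org class — say `schema:Dataset` — and find it
simultaneously too broad and too narrow for their domain. The standard remedy
is a *profile*: a new class in a project namespace that subclasses the
Schema.org class, inherits all of its properties, adds the missing
domain-specific ones, and pins down data-quality rules the base vocabulary
cannot express — **marginality** (is a property required, recommended, or
optional?), **cardinality** (one value or many?), and **ontology
constraints** (e.g. values must be NCBI Taxonomy terms). schemaforge is a
library + CLI that implements this profile-engineering workflow end to end,
with a file-backed searchable registry instead of a hosted service.

## The model

A schema document for namespace `ns` is a JSON-LD file in the RDF Schema
dialect used by Schema.org's own vocabulary dump:

* `@context` binds CURIE prefixes to IRI bases,
* `@graph` holds nodes typed `rdfs:Class` (with `rdfs:subClassOf` parent
  links) and `rdf:Property` (with `schema:domainIncludes` /
  `schema:rangeIncludes` membership),
* each class may embed a `$validation` block: a restricted JSON Schema
  (draft-07 keyword subset) over property local names, plus `required` /
  `recommended` lists.

Classes form a DAG; the *effective* property set of a class C is

```
eff(C) = ⋃ { props(A) : A ∈ {C} ∪ ancestors(C) }
```

with local-name collisions resolved child-most first, then left-parent
first. Validation blocks compile the same way down the chain: required sets
union monotonically, per-property rules resolve child-most. Cardinality
"many" for a rule R is expressed exactly as `oneOf[R, {array of R, minItems
1}]`. A registry accepts a document iff it defines ≥ 1 class, at least one
class is rooted in the `schema:` hierarchy, and its namespace is fresh —
classless, property-only vocabularies are refused (their properties can
still be borrowed by class-based schemas).

The bundled fixtures reconstruct the COVID-19 **Outbreak** schema — 22
classes, of which six are principal (`Analysis`, `Dataset`, `ClinicalTrial`,
`ComputationalTool`, `Protocol`, `Publication`) — on top of a curated
16-class Schema.org snapshot rooted at `schema:Thing`.

## Worked example

```bash
# install the bundled Outbreak schema into a local registry store
schemaforge --registry store fixtures install
# -> installed 'outbreak' (22 classes)

schemaforge --registry store view outbreak:Protocol
# -> outbreak:Protocol
#      parent chains:
#        outbreak:Protocol -> schema:HowTo -> schema:CreativeWork -> schema:Thing
#      effective properties (20): ...

schemaforge --registry store search Dataset
# -> outbreak:Dataset  (outbreak)
#    schema:Dataset  (schema)

schemaforge --registry store compare schema:Dataset outbreak:Dataset
# -> shared (15): alternateName, author, citation, ..., variableMeasured
#    unique to outbreak:Dataset (6): citationObject, dataDownload,
#      infectiousAgent, monetaryGrant, organization, person

schemaforge --registry store fixtures example outbreak:Dataset --seed 3 > inst.json
cat inst.json
# -> {"@context": ..., "@type": "outbreak:Dataset",
#     "description": "assay", "infectiousAgent": {"identifier": "NCBITaxon:99"},
#     "name": "alpha metadata omicron"}

schemaforge --registry store validate inst.json -c outbreak:Dataset
# -> VALID (exit 0); deleting infectiousAgent yields
#    "violation at infectiousAgent [required]" and exit 1
```

The same flow is available as library calls (`extend_class`,
`compile_validation`, `validate_document`, `Registry.register`, ...); the
validator output shows, per violation, the instance path and the JSON Schema
keyword that failed, while missing *recommended* properties surface as
warnings that never affect validity.

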
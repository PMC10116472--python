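# Methods

This note records how schemaforge models class-based metadata schemas, the
design choices made where the conventions in the wild are silent, and what
the bundled fixtures do and do not establish about real vocabularies.

## Document model and canonical form

A schema document is one namespace's export: a `@context` (prefix → absolute
IRI base), an explicit `x:namespace` token, and a `@graph` of `rdfs:Class`
and `rdf:Property` nodes. Parent links use `rdfs:subClassOf` as
`{"@id": curie}` objects; property membership uses `schema:domainIncludes` /
`schema:rangeIncludes`; labels and descriptions use `rdfs:label` /
`rdfs:comment`. Two non-RDF annotations live under the `x:` prefix:
`x:principal` (boolean; marks top-level resource types as opposed to support
classes; absent means false) and `x:namespace`. The namespace annotation
exists because a document *composed* from several vocabularies (via
`merge_schemas`) contains node ids under multiple prefixes, so the
namespace token cannot be recovered from the nodes alone; without it,
parse∘serialize would not be the identity on merged documents. On input the
annotation is optional: a document whose nodes share one prefix, or whose
context binds exactly one non-reserved prefix, infers its namespace.

Serialization is canonical and total-ordered: UTF-8, two-space indent,
top-level keys `@context` (prefixes sorted), `x:namespace`, `@graph`
(classes then properties, each in document order), per-node key order fixed
(`@id`, `@type`, `rdfs:label`, `rdfs:comment`, `rdfs:subClassOf`,
`schema:domainIncludes`, `schema:rangeIncludes`, `x:principal`,
`$validation`), and rule nodes key-sorted recursively. Equal documents
serialize byte-identically, which is what makes the file-backed registry
diffable and the round-trip property testable at the byte level.
Identifiers are case-sensitive; violations of the UpperCamelCase-class /
lowerCamelCase-property convention warn but never fail. The stdlib JSON
machinery is used directly rather than a generic JSON-LD processor, because
the dialect is fixed and the non-RDF annotations and byte-determinism are
part of the contract; conformance of the emitted JSON-LD is cross-checked
in the tests by parsing serialized documents with rdflib and comparing the
resulting `rdfs:subClassOf` triples.

## Inheritance

Classes form a directed acyclic graph (cycles are rejected with the cycle
named; multiple inheritance is allowed, as Schema.org itself has it). The
effective property set of a class is the union of properties whose
`domainIncludes` names the class or any ancestor. Local-name collisions
resolve *child-most first, then left-parent first*: precedence is
breadth-first order from the class, first occurrence wins. BFS order was
chosen over preorder DFS because it ranks every direct parent ahead of any
grandparent, which is what "child-most" means in a diamond; a total order
is required for determinism and the tests pin it against an independent
oracle that ranks ancestors by (shortest distance, lexicographically
smallest minimal path).

Parents named but not defined in any loaded document ("dangling") are
tolerated with a warning so users can author before importing every
dependency, but they are dead ends: traversal stops there, and a dangling
`schema:` parent does not make a class count as rooted in Schema.org —
nothing verifiable is known about an undefined identifier, and a typo
should not open the registry gate.

## Validation rules

Each class may embed a rule set: per-property rule nodes drawn from a
restricted draft-07 keyword subset (`type`, `enum`, `pattern`, `format`,
`items`, `oneOf`, `anyOf`, `$ref`, `description`, `minItems`, plus the
object keywords `properties` and `required`, which are needed to express
"an object whose `identifier` matches an ontology's CURIE or IRI
pattern"). Anything outside the subset fails loudly at meta-validation
rather than being ignored, so a rule set that compiles here behaves
identically under any compliant third-party draft-07 validator; rule sets
export to standalone JSON Schema files for exactly that purpose.

Marginality has three levels: required (absence is a violation),
recommended (absence is a warning and never affects validity), optional.
Three levels rather than two, because that is the established profile
practice in life-science schema communities; the warning channel is
isolated in the report type so a consumer that wants binary semantics can
ignore it. Cardinality "many" rewrites a rule R to
`oneOf[R, {type: array, items: R, minItems: 1}]` — exactly, idempotently,
and with no implicit coercion of scalars to singleton lists at validation
time. Marginality and cardinality are orthogonal by construction: one
edits the required/recommended lists, the other the value rule.

Compilation walks the ancestor chain: required/recommended sets union
(required wins ties), per-property rules resolve child-most, `definitions`
merge likewise, and every referenced name must be in the class's effective
property set. In instances, `@context`/`@type`/`@id` are exempt from
unknown-property checks and unknown non-`@` properties warn rather than
violate (permissive by default, matching structured-data practice on the
web); a wrong `@type` is a violation, not an exception. Validation of
`format` covers `uri`, `date`, `date-time`, `email` with pragmatic
patterns; unknown formats are annotations.

Example-markup generation is seeded and deterministic: every required
property gets a value satisfying its rule (pattern-constrained strings are
synthesized by walking the compiled regex tree). Generation raises on
unsatisfiable rules (empty enum) instead of emitting invalid markup.

## Authoring and registry

`extend_class` emits a *new* document that references the base class by
CURIE — nothing is copied, so upstream updates flow through; "selected"
inherited properties appear only in the new class's validation block.
Context merging refuses conflicting prefix bindings rather than renaming,
since silent renaming would corrupt identifiers. Re-registration requires
an explicit `update=True` (CLI `--update`); the registry is a directory of
canonical `.jsonld` files plus a versioned JSON index, with the bundled
Schema.org snapshot pre-registered read-only under `schema`. Search ranks
exact > prefix > substring (case-insensitive over local names, labels,
namespaces), alphabetical within a tier, for reproducible CLI output.
Comparison (2–4 classes, inherited-inclusive by default with an own-only
flag) partitions property *local names*, so an inherited `schema:name`
unifies with the base's `name`; names that resolve to different property
ids across the compared classes are listed as a footnote rather than
silently unified.

## Fixtures and generators

The core vocabulary is a 16-class curated snapshot of Schema.org rooted at
`Thing`, with 3–6 properties per class (every class inherits `name`,
`description`, `identifier`, `url` from `Thing`). Some intermediate classes
of the real hierarchy (`MediaObject`, `Grant`, `Article`) are flattened out
of the parent chains; `MedicalTrial` and `MedicalObservationalStudy` are
included (differing only in `trialDesign` vs `studyDesign`) though the
Outbreak schema does not extend them. This is fixture scope, not a fidelity
claim: tests passing against the snapshot show the machinery is correct,
not that any real-world class's full property inventory is reproduced.

The Outbreak fixture defines the 22 classes with their published
class-to-parent mapping and exactly six principal classes. The published
table lists its source class for `ComputationalTool` as "Software", which
is not a Schema.org class name; `SoftwareApplication` is used.
`DataDownload` appears twice in the published table and is materialized
once, non-principal, consistent with the six-principal-class count.
Support-class usage is encoded as linking properties named after the
support class in lowerCamelCase (e.g. `armGroup` on `ClinicalTrial` ranging
over `outbreak:ArmGroup`; "used in all" support classes attach to all six
principal classes) — the published material names no such properties, so
these names are this package's convention. `outbreak:Dataset` requires
`name`, `description` and `infectiousAgent`, the latter constrained to NCBI
Taxonomy terms (`NCBITaxon:<digits>` CURIEs or OBO PURLs); the real
published schema carries many more properties sourced from external
crosswalks that are out of scope here.

Random schemas are seeded and always acyclic by construction (classes may
take one or two parents among earlier classes only; ~70 % of classes with
own properties carry a validation block whose rules are drawn from a menu
covering every supported rule shape). The labeled corpus generator embeds
ground truth by construction: valid instances come from the example
generator; invalid ones take exactly one named defect — deleted required
key, wrong JSON type, cardinality breach (empty array under "many", array
under "one"), or ontology-pattern breach — each guaranteed to violate the
specific rule it targets. What corpus agreement shows is therefore that
the validator detects each defect class with recall 1 and never flags a
constructed-valid instance; it does not probe rule shapes outside the
supported subset, which fail at compile time instead.

## Problem sizes and numerical choices

The test suite and the acceptance script run the round-trip check on the
two fixtures plus 100 random documents, the inheritance oracle on 200
random graphs of 5–50 nodes (expected number of root paths per node grows
only sub-linearly at these branching settings, keeping exhaustive
enumeration cheap), the labeled corpus at 500 instances with half invalid,
and the registration gate over all eight combinations of its three
conditions. These sizes make the whole suite run in seconds on one CPU
while leaving each statistical check with enough mass that a single
disagreement would fail it; agreement thresholds are exact (any
disagreement is a bug, not tolerance).

## Known limitations

* No JSON-LD 1.1 framing/compaction against arbitrary contexts, no triple
  stores, no TTL/SHACL/ShEx, no remote `$ref` or URL fetching.
* `rangeIncludes` is carried and compared but not reasoned over (no
  range-hierarchy checks), and OWL semantics are out of scope.
* The draft-07 subset omits numeric bounds, `maxItems`, `allOf`, `not`;
  rule sets using them are rejected rather than approximated.
* One namespace per document; multi-namespace composition goes through
  `merge_schemas`.
* The registry is single-user and local; no authentication or remote sync.
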
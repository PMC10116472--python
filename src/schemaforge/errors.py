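"""Exception and warning hierarchy shared across schemaforge."""

from __future__ import annotations


class SchemaForgeError(Exception):
    """Base class for all schemaforge errors."""


class SchemaError(SchemaForgeError):
    """A schema document violates the data-model contract."""


class ParseError(SchemaError):
    """A JSON-LD schema document could not be parsed."""


class MalformedDocumentError(ParseError):
    """Input is not well-formed JSON, or lacks the @context/@graph structure."""


class MissingContextError(ParseError):
    """Document has no @context block."""


class NodeIdentifierError(ParseError):
    """A graph node has no @id."""


class ContextError(SchemaError):
    """CURIE resolution failure: unknown prefix, empty local name, bad IRI base."""


class InvariantError(SchemaError):
    """A structural invariant of a document or domain type is violated."""


class NamespaceError(InvariantError):
    """The document's namespace token is missing, unresolvable or inconsistent."""


class CycleError(SchemaForgeError):
    """A subclass cycle was found in the class graph."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("subclass cycle: " + " -> ".join(self.cycle + self.cycle[:1]))


class UnknownClassError(SchemaForgeError):
    """A class id was looked up that is not present in the graph/documents."""


class DuplicateDefinitionError(SchemaError):
    """The same identifier is defined twice with differing definitions."""


class ExtensionError(SchemaForgeError):
    """An ExtensionRequest is invalid or cannot be applied."""


class MergeError(SchemaError):
    """Documents cannot be merged (conflicting definitions or prefixes)."""


class RuleError(SchemaForgeError):
    """A validation rule set is malformed (unsupported keyword, bad $ref...)."""


class UnsupportedKeywordError(RuleError):
    """A rule node uses a JSON Schema keyword outside the supported subset."""


class UnknownPropertyError(RuleError):
    """A rule-set edit names a property that has no rule."""


class UnsatisfiableRuleError(RuleError):
    """No instance value can satisfy the rule (e.g. empty enum)."""


class RegistryError(SchemaForgeError):
    """Registry storage or lookup failure."""


class RegistrationError(RegistryError):
    """A document does not meet the registration gate."""


class NamespaceCollisionError(RegistrationError):
    """The namespace is already registered."""


class ComparisonLimitError(SchemaForgeError):
    """compare_classes accepts between 2 and 4 classes."""


class SchemaWarningCategory(UserWarning):
    """Base warning category for non-fatal schema issues."""


class UnknownNodeTypeWarning(SchemaWarningCategory):
    """A @graph node has a @type other than rdfs:Class / rdf:Property."""


class NamingConventionWarning(SchemaWarningCategory):
    """Class not UpperCamelCase or property not lowerCamelCase."""


class DanglingParentWarning(SchemaWarningCategory):
    """A class names a parent that is not defined in any loaded document."""
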
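"""Standard RDF / RDFS / OWL 2 / XSD vocabulary with fixed IDs.

Every store pre-interns the four standard namespaces and their terms in the
order enumerated here, so the resulting ``NsId``/``NodeId`` values are
constants: identical across store instances, configurations, and runs.  Code
elsewhere refers to the module-level constants (``RDF_TYPE``, ``OWL_CLASS``,
...) rather than re-interning strings.

An IRI whose namespace is one of the four standard namespaces but whose term
is *not* in this enumeration is, by definition, a misspelled standard term
(e.g. ``owl:Classs``); the axiom mapper reports these as errors.
"""

from __future__ import annotations

from .ids import NodeId, NsId

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"

#: Standard namespaces in fixed interning order.
STANDARD_NAMESPACES: tuple[str, ...] = (RDF, RDFS, OWL, XSD)

NS_RDF = NsId(0)
NS_RDFS = NsId(1)
NS_OWL = NsId(2)
NS_XSD = NsId(3)

_RDF_TERMS = (
    "type", "Property", "XMLLiteral", "PlainLiteral", "langString",
    "first", "rest", "nil", "List",
    "Statement", "subject", "predicate", "object", "value",
    "Bag", "Seq", "Alt",
)

_RDFS_TERMS = (
    "Resource", "Class", "Literal", "Datatype", "Container",
    "ContainerMembershipProperty", "member",
    "subClassOf", "subPropertyOf", "domain", "range",
    "label", "comment", "seeAlso", "isDefinedBy",
)

_OWL_TERMS = (
    "Ontology", "imports", "versionIRI", "versionInfo",
    "priorVersion", "backwardCompatibleWith", "incompatibleWith",
    "Class", "Thing", "Nothing",
    "ObjectProperty", "DatatypeProperty", "AnnotationProperty",
    "NamedIndividual", "OntologyProperty",
    "topObjectProperty", "bottomObjectProperty",
    "topDataProperty", "bottomDataProperty",
    "Restriction", "onProperty", "someValuesFrom", "allValuesFrom",
    "hasValue", "hasSelf",
    "minCardinality", "maxCardinality", "cardinality",
    "minQualifiedCardinality", "maxQualifiedCardinality",
    "qualifiedCardinality", "onClass", "onDataRange",
    "intersectionOf", "unionOf", "complementOf", "oneOf",
    "datatypeComplementOf", "onDatatype", "withRestrictions",
    "equivalentClass", "disjointWith", "disjointUnionOf",
    "equivalentProperty", "propertyDisjointWith", "inverseOf",
    "propertyChainAxiom", "hasKey",
    "FunctionalProperty", "InverseFunctionalProperty",
    "TransitiveProperty", "SymmetricProperty", "AsymmetricProperty",
    "ReflexiveProperty", "IrreflexiveProperty",
    "sameAs", "differentFrom", "AllDifferent", "distinctMembers",
    "AllDisjointClasses", "AllDisjointProperties", "members",
    "NegativePropertyAssertion", "sourceIndividual",
    "assertionProperty", "targetIndividual", "targetValue",
    "Axiom", "annotatedSource", "annotatedProperty", "annotatedTarget",
    "Annotation", "deprecated", "DeprecatedClass", "DeprecatedProperty",
    "rational", "real",
)

_XSD_TERMS = (
    "string", "boolean", "decimal", "integer", "float", "double",
    "long", "int", "short", "byte",
    "nonNegativeInteger", "nonPositiveInteger",
    "positiveInteger", "negativeInteger",
    "unsignedLong", "unsignedInt", "unsignedShort", "unsignedByte",
    "dateTime", "dateTimeStamp", "date", "time", "duration",
    "gYear", "gMonth", "gDay", "gYearMonth", "gMonthDay",
    "hexBinary", "base64Binary", "anyURI", "language",
    "normalizedString", "token", "Name", "NCName", "NMTOKEN",
    "minInclusive", "maxInclusive", "minExclusive", "maxExclusive",
    "minLength", "maxLength", "length", "pattern",
)

#: (namespace id, fragment) pairs in fixed interning order.
STANDARD_TERMS: tuple[tuple[NsId, str], ...] = tuple(
    [(NS_RDF, t) for t in _RDF_TERMS]
    + [(NS_RDFS, t) for t in _RDFS_TERMS]
    + [(NS_OWL, t) for t in _OWL_TERMS]
    + [(NS_XSD, t) for t in _XSD_TERMS]
)

#: Full IRI string -> constant NodeId for every standard term.
STANDARD_IRIS: dict[str, NodeId] = {
    STANDARD_NAMESPACES[ns] + frag: NodeId(i)
    for i, (ns, frag) in enumerate(STANDARD_TERMS)
}

#: Number of pre-interned standard term nodes.
VOCABULARY_SIZE = len(STANDARD_TERMS)


def _c(iri: str) -> NodeId:
    return STANDARD_IRIS[iri]


RDF_TYPE = _c(RDF + "type")
RDF_FIRST = _c(RDF + "first")
RDF_REST = _c(RDF + "rest")
RDF_NIL = _c(RDF + "nil")
RDF_XML_LITERAL = _c(RDF + "XMLLiteral")
RDF_PLAIN_LITERAL = _c(RDF + "PlainLiteral")
RDF_LANG_STRING = _c(RDF + "langString")

RDFS_SUBCLASSOF = _c(RDFS + "subClassOf")
RDFS_SUBPROPERTYOF = _c(RDFS + "subPropertyOf")
RDFS_DOMAIN = _c(RDFS + "domain")
RDFS_RANGE = _c(RDFS + "range")
RDFS_LABEL = _c(RDFS + "label")
RDFS_COMMENT = _c(RDFS + "comment")
RDFS_SEEALSO = _c(RDFS + "seeAlso")
RDFS_ISDEFINEDBY = _c(RDFS + "isDefinedBy")
RDFS_DATATYPE = _c(RDFS + "Datatype")

OWL_ONTOLOGY = _c(OWL + "Ontology")
OWL_IMPORTS = _c(OWL + "imports")
OWL_VERSION_IRI = _c(OWL + "versionIRI")
OWL_VERSION_INFO = _c(OWL + "versionInfo")
OWL_CLASS = _c(OWL + "Class")
OWL_THING = _c(OWL + "Thing")
OWL_NOTHING = _c(OWL + "Nothing")
OWL_OBJECT_PROPERTY = _c(OWL + "ObjectProperty")
OWL_DATATYPE_PROPERTY = _c(OWL + "DatatypeProperty")
OWL_ANNOTATION_PROPERTY = _c(OWL + "AnnotationProperty")
OWL_NAMED_INDIVIDUAL = _c(OWL + "NamedIndividual")
OWL_RESTRICTION = _c(OWL + "Restriction")
OWL_ON_PROPERTY = _c(OWL + "onProperty")
OWL_SOME_VALUES_FROM = _c(OWL + "someValuesFrom")
OWL_ALL_VALUES_FROM = _c(OWL + "allValuesFrom")
OWL_HAS_VALUE = _c(OWL + "hasValue")
OWL_MIN_CARDINALITY = _c(OWL + "minCardinality")
OWL_MAX_CARDINALITY = _c(OWL + "maxCardinality")
OWL_CARDINALITY = _c(OWL + "cardinality")
OWL_MIN_QUALIFIED_CARDINALITY = _c(OWL + "minQualifiedCardinality")
OWL_MAX_QUALIFIED_CARDINALITY = _c(OWL + "maxQualifiedCardinality")
OWL_QUALIFIED_CARDINALITY = _c(OWL + "qualifiedCardinality")
OWL_ON_CLASS = _c(OWL + "onClass")
OWL_ON_DATA_RANGE = _c(OWL + "onDataRange")
OWL_INTERSECTION_OF = _c(OWL + "intersectionOf")
OWL_UNION_OF = _c(OWL + "unionOf")
OWL_COMPLEMENT_OF = _c(OWL + "complementOf")
OWL_ONE_OF = _c(OWL + "oneOf")
OWL_EQUIVALENT_CLASS = _c(OWL + "equivalentClass")
OWL_DISJOINT_WITH = _c(OWL + "disjointWith")
OWL_FUNCTIONAL_PROPERTY = _c(OWL + "FunctionalProperty")
OWL_INVERSE_FUNCTIONAL_PROPERTY = _c(OWL + "InverseFunctionalProperty")
OWL_TRANSITIVE_PROPERTY = _c(OWL + "TransitiveProperty")
OWL_SYMMETRIC_PROPERTY = _c(OWL + "SymmetricProperty")
OWL_AXIOM = _c(OWL + "Axiom")
OWL_ANNOTATED_SOURCE = _c(OWL + "annotatedSource")
OWL_ANNOTATED_PROPERTY = _c(OWL + "annotatedProperty")
OWL_ANNOTATED_TARGET = _c(OWL + "annotatedTarget")
OWL_DEPRECATED = _c(OWL + "deprecated")
OWL_PRIOR_VERSION = _c(OWL + "priorVersion")
OWL_BACKWARD_COMPATIBLE_WITH = _c(OWL + "backwardCompatibleWith")
OWL_INCOMPATIBLE_WITH = _c(OWL + "incompatibleWith")

XSD_STRING = _c(XSD + "string")
XSD_BOOLEAN = _c(XSD + "boolean")
XSD_DECIMAL = _c(XSD + "decimal")
XSD_INTEGER = _c(XSD + "integer")
XSD_FLOAT = _c(XSD + "float")
XSD_DOUBLE = _c(XSD + "double")
XSD_INT = _c(XSD + "int")
XSD_LONG = _c(XSD + "long")
XSD_NON_NEGATIVE_INTEGER = _c(XSD + "nonNegativeInteger")

#: Annotation properties usable without an explicit declaration.
BUILTIN_ANNOTATION_PROPERTIES = frozenset({
    RDFS_LABEL, RDFS_COMMENT, RDFS_SEEALSO, RDFS_ISDEFINEDBY,
    OWL_VERSION_INFO, OWL_DEPRECATED, OWL_PRIOR_VERSION,
    OWL_BACKWARD_COMPATIBLE_WITH, OWL_INCOMPATIBLE_WITH,
})

#: Datatypes whose literals have plain string semantics (language allowed).
STRINGY_DATATYPES = frozenset({
    XSD_STRING, RDF_PLAIN_LITERAL, RDF_LANG_STRING,
})
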
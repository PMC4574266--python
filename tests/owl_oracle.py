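"""Independent RDF-graph-to-axiom oracle built on rdflib.

This module never touches owlstore's store, parser, or mapper: it parses
RDF/XML with rdflib and maps the resulting graph to structural axiom
tuples with its own traversal code.  Tests compare these tuples with the
ones an adapter (:func:`package_axioms_to_tuples`) derives from owlstore's
structured axioms, so the two routes to the same answer stay fully
separate.

Tuple scheme (shared with the fixtures module's closed-form expectations):

- ``("Ontology", iri_or_None, (import_iri, ...))``
- ``("Declaration", kind, iri)``
- ``("SubClassOf", ce, ce)`` etc., where a class expression ``ce`` is
  ``("C", iri)``, ``("and"|"or", sorted parts)``, ``("not", ce)``,
  ``("oneOf", sorted iris)``, ``("some"|"only", prop, filler)``,
  ``("value", prop, term)``, or ``("min"|"max"|"exactly", n, prop,
  filler_or_None)``.
- literals are ``("lit", lexical, datatype_iri_or_None, lang)`` with
  plain/xsd:string collapsed to ``None``.
"""

from __future__ import annotations

from collections import Counter

from rdflib import OWL, RDF, RDFS, XSD, BNode, Graph, Literal, URIRef
from rdflib.collection import Collection

_DECL_KINDS = {
    OWL.Class: "Class",
    OWL.ObjectProperty: "ObjectProperty",
    OWL.DatatypeProperty: "DataProperty",
    OWL.AnnotationProperty: "AnnotationProperty",
    OWL.NamedIndividual: "NamedIndividual",
    RDFS.Datatype: "Datatype",
}

_BUILTIN_ANNOTATION = {
    RDFS.label, RDFS.comment, RDFS.seeAlso, RDFS.isDefinedBy,
    OWL.versionInfo, OWL.deprecated, OWL.priorVersion,
    OWL.backwardCompatibleWith, OWL.incompatibleWith,
}

_CHARACTERISTICS = {
    OWL.FunctionalProperty: "Functional",
    OWL.InverseFunctionalProperty: "InverseFunctional",
    OWL.TransitiveProperty: "Transitive",
    OWL.SymmetricProperty: "Symmetric",
}

_STRING_DT = {None, XSD.string, RDF.langString}


class OracleError(Exception):
    """The oracle met a construct outside its supported subset."""


def _lit(o: Literal) -> tuple:
    dt = o.datatype if o.datatype not in _STRING_DT else None
    return ("lit", str(o), str(dt) if dt else None, o.language or "")


def _term(o) -> object:
    if isinstance(o, URIRef):
        return str(o)
    if isinstance(o, Literal):
        return _lit(o)
    return "*blank*"


def _class_expr(g: Graph, node, decls) -> tuple:
    if isinstance(node, URIRef):
        return ("C", str(node))
    if not isinstance(node, BNode):
        raise OracleError(f"literal as class expression: {node!r}")
    for pred, kind in ((OWL.intersectionOf, "and"), (OWL.unionOf, "or")):
        head = g.value(node, pred)
        if head is not None:
            members = [
                _class_expr(g, m, decls) for m in Collection(g, head)
            ]
            return (kind, tuple(sorted(members, key=repr)))
    comp = g.value(node, OWL.complementOf)
    if comp is not None:
        return ("not", _class_expr(g, comp, decls))
    one = g.value(node, OWL.oneOf)
    if one is not None:
        return ("oneOf", tuple(sorted(str(m) for m in Collection(g, one))))
    if (node, RDF.type, OWL.Restriction) in g:
        return _restriction(g, node, decls)
    raise OracleError(f"unrecognized expression node {node!r}")


def _restriction(g: Graph, node, decls) -> tuple:
    prop = g.value(node, OWL.onProperty)
    if prop is None:
        raise OracleError("restriction without owl:onProperty")
    data = decls.get(prop) == "DataProperty"

    def filler(v):
        if data:
            return ("D", str(v))
        return _class_expr(g, v, decls)

    for pred, kind in (
        (OWL.someValuesFrom, "some"), (OWL.allValuesFrom, "only"),
    ):
        v = g.value(node, pred)
        if v is not None:
            return (kind, str(prop), filler(v))
    v = g.value(node, OWL.hasValue)
    if v is not None:
        return ("value", str(prop), _term(v))
    for pred, kind, qualified in (
        (OWL.minCardinality, "min", False),
        (OWL.maxCardinality, "max", False),
        (OWL.cardinality, "exactly", False),
        (OWL.minQualifiedCardinality, "min", True),
        (OWL.maxQualifiedCardinality, "max", True),
        (OWL.qualifiedCardinality, "exactly", True),
    ):
        v = g.value(node, pred)
        if v is not None:
            f = None
            if qualified:
                target = g.value(
                    node, OWL.onDataRange if data else OWL.onClass
                )
                f = filler(target)
            return (kind, int(v), str(prop), f)
    raise OracleError("restriction without a recognized filler key")


def oracle_axioms(data, base: str = "http://example.org/base") -> Counter:
    """Map an RDF/XML document to a multiset of structural axiom tuples."""
    g = Graph()
    g.parse(data=data, format="xml", publicID=base)

    decls: dict = {}
    out: list[tuple] = []
    for s, _p, o in g.triples((None, RDF.type, None)):
        kind = _DECL_KINDS.get(o)
        if kind is not None and isinstance(s, URIRef):
            decls[s] = kind
            out.append(("Declaration", kind, str(s)))

    header = g.value(None, RDF.type, OWL.Ontology)
    header_subjects = set()
    if header is not None:
        header_subjects.add(header)
        imports = tuple(sorted(str(i) for i in g.objects(header, OWL.imports)))
        out.append((
            "Ontology",
            str(header) if isinstance(header, URIRef) else None,
            imports,
        ))

    for s, o in g.subject_objects(RDFS.subClassOf):
        out.append(
            ("SubClassOf", _class_expr(g, s, decls), _class_expr(g, o, decls))
        )
    for s, o in g.subject_objects(OWL.equivalentClass):
        pair = sorted(
            (_class_expr(g, s, decls), _class_expr(g, o, decls)), key=repr
        )
        out.append(("EquivalentClasses", *pair))
    for s, o in g.subject_objects(OWL.disjointWith):
        pair = sorted(
            (_class_expr(g, s, decls), _class_expr(g, o, decls)), key=repr
        )
        out.append(("DisjointClasses", *pair))

    for s, o in g.subject_objects(RDFS.subPropertyOf):
        kind = decls.get(s)
        name = {
            "ObjectProperty": "SubObjectPropertyOf",
            "DataProperty": "SubDataPropertyOf",
            "AnnotationProperty": "SubAnnotationPropertyOf",
        }.get(kind)
        if name is None:
            raise OracleError(f"subPropertyOf on undeclared {s}")
        out.append((name, str(s), str(o)))
    for pred, which in ((RDFS.domain, "Domain"), (RDFS.range, "Range")):
        for s, o in g.subject_objects(pred):
            kind = decls.get(s)
            if kind == "ObjectProperty":
                out.append(
                    (f"ObjectProperty{which}", str(s),
                     _class_expr(g, o, decls))
                )
            elif kind == "DataProperty":
                if which == "Domain":
                    out.append(
                        ("DataPropertyDomain", str(s),
                         _class_expr(g, o, decls))
                    )
                else:
                    out.append(("DataPropertyRange", str(s), str(o)))
            elif kind == "AnnotationProperty":
                out.append((f"AnnotationProperty{which}", str(s), str(o)))
            else:
                raise OracleError(f"domain/range on undeclared {s}")

    for s, _p, o in g.triples((None, RDF.type, None)):
        ch = _CHARACTERISTICS.get(o)
        if ch is not None:
            if decls.get(s) == "DataProperty":
                out.append((f"{ch}DataProperty", str(s)))
            else:
                out.append((f"{ch}ObjectProperty", str(s)))
            continue
        if o in _DECL_KINDS or o in (OWL.Ontology, OWL.Restriction, OWL.Axiom):
            continue
        if isinstance(o, URIRef) and decls.get(o) != "Class":
            raise OracleError(f"rdf:type with undeclared class {o}")
        if isinstance(s, BNode):
            continue  # expression anchors
        out.append(
            ("ClassAssertion", _class_expr(g, o, decls), _term(s))
        )

    for s, p, o in g:
        kind = decls.get(p)
        if kind == "ObjectProperty":
            out.append(("ObjectPropertyAssertion", str(p), _term(s), _term(o)))
        elif kind == "DataProperty":
            out.append(("DataPropertyAssertion", str(p), _term(s), _term(o)))
        elif kind == "AnnotationProperty" or p in _BUILTIN_ANNOTATION:
            if s in header_subjects:
                continue  # ontology-header annotation, part of the header
            out.append(("AnnotationAssertion", str(p), _term(s), _term(o)))
    return Counter(out)


def oracle_triples(data, base: str = "http://example.org/base") -> Graph:
    """Parse RDF/XML with rdflib, for triple-level agreement checks."""
    g = Graph()
    g.parse(data=data, format="xml", publicID=base)
    return g
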
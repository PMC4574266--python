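"""Shared test helpers: adapters between owlstore structures and the
neutral tuple/graph forms used for oracle comparisons."""

from __future__ import annotations

from collections import Counter

from rdflib import BNode, Graph, Literal, URIRef

from owlstore import Axiom, ClassExpr, TripleStore
from owlstore import vocabulary as voc
from owlstore.nodes import NodeBlank, NodeIri, NodeLiteral
from owlstore.rdfxml import BlankRef, IriRef, LiteralRef, RawStatement

_STRING_DT_IRIS = {voc.XSD + "string", voc.RDF + "langString"}


def _term_tuple(store: TripleStore, node_id) -> object:
    node = store[node_id]
    if isinstance(node, NodeIri):
        return store.iri_str(node_id)
    if isinstance(node, NodeBlank):
        return "*blank*"
    lit: NodeLiteral = node
    dt = store.iri_str(lit.datatype)
    dt_out = None if dt in _STRING_DT_IRIS else dt
    return ("lit", lit.lexical, dt_out, lit.language)


def _ce_tuple(store: TripleStore, ce: ClassExpr) -> tuple:
    if ce.kind == "named":
        return ("C", store.iri_str(ce.node))
    if ce.kind in ("and", "or"):
        parts = tuple(
            sorted((_ce_tuple(store, p) for p in ce.parts), key=repr)
        )
        return (ce.kind, parts)
    if ce.kind == "not":
        return ("not", _ce_tuple(store, ce.parts[0]))
    if ce.kind == "oneOf":
        return ("oneOf", tuple(sorted(store.iri_str(m) for m in ce.parts)))
    prop = store.iri_str(ce.prop)
    if ce.kind in ("some", "only"):
        filler = (
            ("D", store.iri_str(ce.filler)) if ce.data
            else _ce_tuple(store, ce.filler)
        )
        return (ce.kind, prop, filler)
    if ce.kind == "value":
        return ("value", prop, _term_tuple(store, ce.filler))
    filler = None
    if ce.filler is not None:
        filler = (
            ("D", store.iri_str(ce.filler)) if ce.data
            else _ce_tuple(store, ce.filler)
        )
    return (ce.kind, ce.n, prop, filler)


def _operand_tuple(store: TripleStore, op) -> object:
    if isinstance(op, ClassExpr):
        return _ce_tuple(store, op)
    return _term_tuple(store, op)


def axiom_to_tuple(store: TripleStore, axiom: Axiom) -> tuple:
    """Convert one structured owlstore axiom to the neutral tuple scheme."""
    if axiom.kind == "Ontology":
        iri, _version, imports = axiom.operands
        return (
            "Ontology",
            store.iri_str(iri) if iri is not None else None,
            tuple(sorted(store.iri_str(i) for i in imports)),
        )
    if axiom.kind == "Declaration":
        kind, node = axiom.operands
        return ("Declaration", kind, store.iri_str(node))
    ops = [_operand_tuple(store, op) for op in axiom.operands]
    if axiom.kind in ("EquivalentClasses", "DisjointClasses"):
        ops = sorted(ops, key=repr)
    return (axiom.kind, *ops)


def package_axioms_to_tuples(store: TripleStore, axioms) -> Counter:
    """Multiset of neutral tuples for a list of owlstore axioms."""
    return Counter(axiom_to_tuple(store, a) for a in axioms)


def statements_to_graph(statements) -> Graph:
    """Build an rdflib Graph from owlstore's parsed raw statements, so two
    parses can be compared by graph isomorphism."""
    g = Graph()
    blanks: dict[str, BNode] = {}

    def term(t):
        if isinstance(t, IriRef):
            return URIRef(t.iri)
        if isinstance(t, BlankRef):
            return blanks.setdefault(t.label, BNode())
        lit: LiteralRef = t
        if lit.language:
            return Literal(lit.lexical, lang=lit.language)
        if lit.datatype is None:
            return Literal(lit.lexical)
        return Literal(lit.lexical, datatype=URIRef(lit.datatype))

    for st in statements:
        g.add((term(st.subj), URIRef(st.pred), term(st.obj)))
    return g


def expected_statements_to_graph(expected) -> Graph:
    """Build an rdflib Graph from a fixture's expected statement tuples."""
    raw = []
    for s, p, o in expected:
        subj = BlankRef(s[2:]) if s.startswith("_:") else IriRef(s)
        if isinstance(o, tuple):
            obj = LiteralRef(o[1], o[2], o[3])
        elif o.startswith("_:"):
            obj = BlankRef(o[2:])
        else:
            obj = IriRef(o)
        raw.append(RawStatement(subj, p, obj))
    return statements_to_graph(raw)
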
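"""Strict translation of stored RDF triples into OWL 2 axioms.

The mapper follows the standard reverse mapping from RDF graphs to the
OWL 2 structural specification, in two passes: entity declarations first,
then axiom triples, resolving class expressions anchored at blank nodes
(intersections, unions, complements, enumerations, and property
restrictions) by searching the store.  Every triple in scope must be
consumed exactly once — as a declaration, an axiom trigger, part of an
expression or list structure, or an annotation; anything left over is an
error, as is any undeclared predicate or any misspelling of a standard
RDF/RDFS/OWL/XSD term (e.g. ``owl:Classs``).  All errors abort the whole
translation: no partial axiom list is ever observable.

Axioms serialize deterministically to OWL 2 functional-style syntax via
:func:`serialize_functional`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from . import vocabulary as voc
from .ids import DocId, NodeId
from .nodes import NodeBlank, NodeIri, NodeLiteral
from .store import Triple, TripleStore


class MappingError(Exception):
    """Triple-to-axiom translation failure; aborts the whole translation.

    ``kind`` classifies the failure: ``undeclared`` (predicate or entity
    used without a declaration), ``misspelled`` (unknown term in a
    standard namespace), ``unsupported`` (recognized but unsupported OWL
    construct), ``conflict`` (incompatible declarations), ``structure``
    (malformed expression, list, or leftover triples).
    """

    def __init__(self, kind: str, message: str):
        self.kind = kind
        super().__init__(f"{kind}: {message}")
        self.message = message


DECLARATION_KINDS = {
    voc.OWL_CLASS: "Class",
    voc.OWL_OBJECT_PROPERTY: "ObjectProperty",
    voc.OWL_DATATYPE_PROPERTY: "DataProperty",
    voc.OWL_ANNOTATION_PROPERTY: "AnnotationProperty",
    voc.OWL_NAMED_INDIVIDUAL: "NamedIndividual",
    voc.RDFS_DATATYPE: "Datatype",
}

_CHARACTERISTICS = {
    voc.OWL_FUNCTIONAL_PROPERTY: "Functional",
    voc.OWL_INVERSE_FUNCTIONAL_PROPERTY: "InverseFunctional",
    voc.OWL_TRANSITIVE_PROPERTY: "Transitive",
    voc.OWL_SYMMETRIC_PROPERTY: "Symmetric",
}

_UNSUPPORTED_TYPE_OBJECTS = {
    "AllDifferent", "AllDisjointClasses", "AllDisjointProperties",
    "NegativePropertyAssertion", "AsymmetricProperty", "ReflexiveProperty",
    "IrreflexiveProperty", "DeprecatedClass", "DeprecatedProperty",
}

_UNSUPPORTED_PREDICATES = {
    "sameAs", "differentFrom", "inverseOf", "propertyChainAxiom", "hasKey",
    "equivalentProperty", "propertyDisjointWith", "disjointUnionOf",
    "hasSelf", "datatypeComplementOf", "onDatatype", "withRestrictions",
    "distinctMembers", "members", "sourceIndividual", "assertionProperty",
    "targetIndividual", "targetValue",
}


_EXPRESSION_PREDICATES = frozenset({
    voc.OWL_INTERSECTION_OF, voc.OWL_UNION_OF, voc.OWL_COMPLEMENT_OF,
    voc.OWL_ONE_OF, voc.OWL_ON_PROPERTY, voc.OWL_SOME_VALUES_FROM,
    voc.OWL_ALL_VALUES_FROM, voc.OWL_HAS_VALUE, voc.OWL_MIN_CARDINALITY,
    voc.OWL_MAX_CARDINALITY, voc.OWL_CARDINALITY,
    voc.OWL_MIN_QUALIFIED_CARDINALITY, voc.OWL_MAX_QUALIFIED_CARDINALITY,
    voc.OWL_QUALIFIED_CARDINALITY, voc.OWL_ON_CLASS, voc.OWL_ON_DATA_RANGE,
    voc.RDF_FIRST, voc.RDF_REST,
})


class Declarations:
    """Entity-kind table built from ``rdf:type`` declaration triples.

    Punning across Class / NamedIndividual / Datatype is permitted; a node
    declared both ObjectProperty and DataProperty is an error.  Built-in
    vocabulary (owl:Thing, XSD datatypes, standard annotation properties,
    ...) is pre-declared.
    """

    def __init__(self, store: TripleStore):
        self._store = store
        self._kinds: dict[NodeId, set[str]] = {}
        for nid in (voc.OWL_THING, voc.OWL_NOTHING):
            self._kinds[nid] = {"Class"}
        for nid in voc.BUILTIN_ANNOTATION_PROPERTIES:
            self._kinds[nid] = {"AnnotationProperty"}
        for i, (ns, _frag) in enumerate(voc.STANDARD_TERMS):
            if ns == voc.NS_XSD:
                self._kinds.setdefault(NodeId(i), set()).add("Datatype")
        for nid in (voc.RDF_PLAIN_LITERAL, voc.RDF_LANG_STRING,
                    voc.RDF_XML_LITERAL):
            self._kinds.setdefault(nid, set()).add("Datatype")

    def add(self, node: NodeId, kind: str) -> None:
        kinds = self._kinds.setdefault(node, set())
        kinds.add(kind)
        if "ObjectProperty" in kinds and "DataProperty" in kinds:
            raise MappingError(
                "conflict",
                f"{self._store.node_str(node)} declared both ObjectProperty "
                "and DataProperty",
            )

    def has(self, node: NodeId, kind: str) -> bool:
        return kind in self._kinds.get(node, ())

    def kinds_of(self, node: NodeId) -> frozenset:
        return frozenset(self._kinds.get(node, ()))


@dataclass(frozen=True)
class ClassExpr:
    """A class expression: named class, boolean combination, enumeration,
    or property restriction."""

    kind: str  # named|and|or|not|oneOf|some|only|value|min|max|exactly
    node: Optional[NodeId] = None          # named class
    parts: tuple = ()                      # sub-expressions / individuals
    prop: Optional[NodeId] = None          # restriction property
    filler: object = None                  # ClassExpr | NodeId | None
    n: Optional[int] = None                # cardinality
    data: bool = False                     # data (vs object) restriction


@dataclass
class Axiom:
    """A structured OWL 2 axiom with optional axiom-level annotations."""

    kind: str
    operands: tuple
    annotations: tuple = field(default_factory=tuple)


# --------------------------------------------------------------------------
# scope: a subset of triples with exactly-once consumption accounting
# --------------------------------------------------------------------------


class _Scope:
    def __init__(self, store: TripleStore, triples: Sequence[Triple]):
        self.store = store
        self.triples = list(triples)
        self.consumed = [False] * len(self.triples)
        self.by_s: dict[int, list[int]] = {}
        self.by_sp: dict[tuple[int, int], list[int]] = {}
        for i, t in enumerate(self.triples):
            self.by_s.setdefault(t.subj, []).append(i)
            self.by_sp.setdefault((t.subj, t.pred), []).append(i)

    def sp(self, s: NodeId, p: NodeId) -> list[int]:
        return [
            i for i in self.by_sp.get((int(s), int(p)), [])
            if not self.consumed[i]
        ]

    def subject_triples(self, s: NodeId) -> list[int]:
        return [i for i in self.by_s.get(int(s), []) if not self.consumed[i]]

    def consume(self, i: int) -> None:
        self.consumed[i] = True

    def leftovers(self) -> list[Triple]:
        return [t for i, t in enumerate(self.triples) if not self.consumed[i]]


def _scope_for(
    store: TripleStore, doc: Optional[DocId], triples=None
) -> _Scope:
    if triples is not None:
        return _Scope(store, triples)
    if doc is None:
        return _Scope(store, store.triples)
    return _Scope(store, [t for t in store.triples if t.doc == doc])


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def check_standard_terms(store: TripleStore, triples: Sequence[Triple]) -> None:
    """Reject IRIs in the rdf/rdfs/owl/xsd namespaces that are not part of
    the standard vocabulary (misspellings such as ``owl:Classs``)."""
    seen: set[int] = set()
    for t in triples:
        for nid in (t.subj, t.pred, t.obj):
            if nid in seen:
                continue
            seen.add(nid)
            if nid >= voc.VOCABULARY_SIZE:
                node = store[NodeId(nid)]
                if isinstance(node, NodeIri) and node.ns < len(
                    voc.STANDARD_NAMESPACES
                ):
                    raise MappingError(
                        "misspelled",
                        f"misspelled standard term "
                        f"<{store.iri_str(NodeId(nid))}>",
                    )


def collect_declarations(
    store: TripleStore,
    triples: Optional[Sequence[Triple]] = None,
    scope: Optional[_Scope] = None,
) -> Declarations:
    """Record every ``(x, rdf:type, K)`` with a declarable kind K.

    Conflicting kinds (ObjectProperty vs DataProperty) raise a
    :class:`MappingError`.  When called with a live scope (internal use),
    the declaration triples are consumed.
    """
    own_scope = scope is None
    if own_scope:
        scope = _scope_for(store, None, triples)
    decls = Declarations(store)
    for i, t in enumerate(scope.triples):
        if scope.consumed[i] or t.pred != voc.RDF_TYPE:
            continue
        kind = DECLARATION_KINDS.get(t.obj)
        if kind is None:
            continue
        if isinstance(store[t.subj], NodeIri):
            decls.add(t.subj, kind)
            if not own_scope:
                scope.consume(i)
    return decls


def parse_rdf_list(
    store: TripleStore,
    head: NodeId,
    scope: Optional[_Scope] = None,
) -> list[NodeId]:
    """Follow ``rdf:first``/``rdf:rest`` from *head* to ``rdf:nil``.

    Returns the member NodeIds in order.  Malformed structure — missing or
    duplicated first/rest, cycles, or tails shared with an already-parsed
    list — raises :class:`MappingError`.
    """
    if scope is None:
        scope = _scope_for(store, None)
    members: list[NodeId] = []
    visited: set[int] = set()
    node = head
    while node != voc.RDF_NIL:
        if int(node) in visited:
            raise MappingError(
                "structure", f"cycle in RDF list at {store.node_str(node)}"
            )
        visited.add(int(node))
        firsts = scope.sp(node, voc.RDF_FIRST)
        rests = scope.sp(node, voc.RDF_REST)
        if len(firsts) != 1 or len(rests) != 1:
            raise MappingError(
                "structure",
                f"malformed RDF list node {store.node_str(node)} "
                f"({len(firsts)} rdf:first, {len(rests)} rdf:rest)",
            )
        scope.consume(firsts[0])
        scope.consume(rests[0])
        members.append(scope.triples[firsts[0]].obj)
        node = scope.triples[rests[0]].obj
    return members


class _Mapper:
    def __init__(self, store: TripleStore, scope: _Scope):
        self.store = store
        self.scope = scope
        self.decls: Declarations = Declarations(store)
        self.axioms: list[Axiom] = []
        self.by_trigger: dict[tuple[int, int, int], Axiom] = {}
        self._anchored: set[int] = set()
        self._in_progress: set[int] = set()

    # -- class expressions --------------------------------------------------

    def class_expression(self, root: NodeId) -> ClassExpr:
        store = self.store
        node = store[root]
        if isinstance(node, NodeIri):
            if not self.decls.has(root, "Class"):
                raise MappingError(
                    "undeclared",
                    f"undeclared class {store.node_str(root)}",
                )
            return ClassExpr("named", node=root)
        if isinstance(node, NodeLiteral):
            raise MappingError(
                "structure",
                f"literal {store.node_str(root)} used as a class expression",
            )
        if int(root) in self._anchored:
            raise MappingError(
                "structure",
                f"blank node {store.node_str(root)} anchors more than one "
                "expression",
            )
        if int(root) in self._in_progress:
            raise MappingError(
                "structure",
                f"cyclic class expression at {store.node_str(root)}",
            )
        self._in_progress.add(int(root))
        try:
            expr = self._blank_expression(root)
        finally:
            self._in_progress.discard(int(root))
        self._anchored.add(int(root))
        return expr

    def _blank_expression(self, root: NodeId) -> ClassExpr:
        store, scope = self.store, self.scope
        pending = scope.subject_triples(root)
        preds = {}
        for i in pending:
            preds.setdefault(scope.triples[i].pred, []).append(i)

        def take(pred: NodeId) -> Optional[int]:
            hits = preds.get(pred)
            if not hits:
                return None
            if len(hits) > 1:
                raise MappingError(
                    "structure",
                    f"{store.node_str(root)} has multiple "
                    f"{store.node_str(pred)} triples",
                )
            i = hits.pop(0)
            del preds[pred]
            scope.consume(i)
            return i

        def finish(expr: ClassExpr) -> ClassExpr:
            # a plain rdf:type owl:Class alongside a boolean operator is
            # tolerated (common serializer output); anything else is extra
            type_hits = preds.get(voc.RDF_TYPE, [])
            for i in list(type_hits):
                if scope.triples[i].obj in (voc.OWL_CLASS, voc.OWL_RESTRICTION):
                    scope.consume(i)
                    type_hits.remove(i)
            if not type_hits:
                preds.pop(voc.RDF_TYPE, None)
            leftovers = [i for hits in preds.values() for i in hits]
            if leftovers:
                t = scope.triples[leftovers[0]]
                raise MappingError(
                    "structure",
                    f"unconsumed triple on expression node "
                    f"{store.node_str(root)}: predicate "
                    f"{store.node_str(t.pred)}",
                )
            return expr

        for pred, kind in (
            (voc.OWL_INTERSECTION_OF, "and"),
            (voc.OWL_UNION_OF, "or"),
        ):
            i = take(pred)
            if i is not None:
                members = parse_rdf_list(
                    store, scope.triples[i].obj, scope
                )
                if len(members) < 2:
                    raise MappingError(
                        "structure",
                        f"{store.node_str(pred)} list needs >=2 members",
                    )
                parts = tuple(self.class_expression(m) for m in members)
                return finish(ClassExpr(kind, parts=parts))
        i = take(voc.OWL_COMPLEMENT_OF)
        if i is not None:
            return finish(
                ClassExpr(
                    "not",
                    parts=(self.class_expression(scope.triples[i].obj),),
                )
            )
        i = take(voc.OWL_ONE_OF)
        if i is not None:
            members = parse_rdf_list(store, scope.triples[i].obj, scope)
            for m in members:
                if isinstance(store[m], NodeLiteral):
                    raise MappingError(
                        "structure",
                        "literal in owl:oneOf class enumeration",
                    )
            return finish(ClassExpr("oneOf", parts=tuple(members)))
        if any(
            scope.triples[i].obj == voc.OWL_RESTRICTION
            for i in preds.get(voc.RDF_TYPE, [])
        ):
            return finish(self._restriction(root, take))
        raise MappingError(
            "structure",
            f"blank node {store.node_str(root)} is not a recognized class "
            "expression",
        )

    def _restriction(self, root: NodeId, take) -> ClassExpr:
        store = self.store
        scope = self.scope
        i_prop = take(voc.OWL_ON_PROPERTY)
        if i_prop is None:
            raise MappingError(
                "structure",
                f"restriction {store.node_str(root)} has no owl:onProperty",
            )
        prop = scope.triples[i_prop].obj
        if self.decls.has(prop, "ObjectProperty"):
            data = False
        elif self.decls.has(prop, "DataProperty"):
            data = True
        else:
            raise MappingError(
                "undeclared",
                f"restriction on undeclared property {store.node_str(prop)}",
            )
        filler_keys = (
            (voc.OWL_SOME_VALUES_FROM, "some"),
            (voc.OWL_ALL_VALUES_FROM, "only"),
            (voc.OWL_HAS_VALUE, "value"),
            (voc.OWL_MIN_CARDINALITY, "min"),
            (voc.OWL_MAX_CARDINALITY, "max"),
            (voc.OWL_CARDINALITY, "exactly"),
            (voc.OWL_MIN_QUALIFIED_CARDINALITY, "min"),
            (voc.OWL_MAX_QUALIFIED_CARDINALITY, "max"),
            (voc.OWL_QUALIFIED_CARDINALITY, "exactly"),
        )
        hits = []
        for pred, kind in filler_keys:
            i = take(pred)
            if i is not None:
                hits.append((pred, kind, scope.triples[i].obj))
        if len(hits) != 1:
            raise MappingError(
                "structure",
                f"restriction {store.node_str(root)} has {len(hits)} filler "
                "keys (exactly one required)",
            )
        pred, kind, obj = hits[0]
        qualified = pred in (
            voc.OWL_MIN_QUALIFIED_CARDINALITY,
            voc.OWL_MAX_QUALIFIED_CARDINALITY,
            voc.OWL_QUALIFIED_CARDINALITY,
        )
        if kind in ("some", "only"):
            if data:
                filler = self._datatype(obj)
            else:
                filler = self.class_expression(obj)
            return ClassExpr(kind, prop=prop, filler=filler, data=data)
        if kind == "value":
            node = store[obj]
            if data and not isinstance(node, NodeLiteral):
                raise MappingError(
                    "structure", "owl:hasValue on a data property needs a "
                    "literal",
                )
            if not data and isinstance(node, NodeLiteral):
                raise MappingError(
                    "structure", "owl:hasValue on an object property needs "
                    "an individual",
                )
            return ClassExpr("value", prop=prop, filler=obj, data=data)
        n = self._cardinality(obj)
        filler = None
        i_q = take(voc.OWL_ON_CLASS if not data else voc.OWL_ON_DATA_RANGE)
        if i_q is not None:
            if not qualified:
                raise MappingError(
                    "structure",
                    "owl:onClass/onDataRange with an unqualified cardinality",
                )
            target = scope.triples[i_q].obj
            filler = (
                self._datatype(target) if data
                else self.class_expression(target)
            )
        elif qualified:
            raise MappingError(
                "structure",
                "qualified cardinality without owl:onClass/owl:onDataRange",
            )
        return ClassExpr(kind, prop=prop, filler=filler, n=n, data=data)

    def _cardinality(self, obj: NodeId) -> int:
        node = self.store[obj]
        if isinstance(node, NodeLiteral) and isinstance(node.value, int) \
                and not isinstance(node.value, bool) and node.value >= 0:
            return node.value
        raise MappingError(
            "structure",
            f"cardinality value {self.store.node_str(obj)} is not a "
            "non-negative integer",
        )

    def _datatype(self, obj: NodeId) -> NodeId:
        if not self.decls.has(obj, "Datatype"):
            raise MappingError(
                "undeclared",
                f"undeclared datatype {self.store.node_str(obj)}",
            )
        return obj

    # -- reified axiom annotations -------------------------------------------

    def _collect_reified(self) -> dict[tuple, list]:
        store, scope = self.store, self.scope
        out: dict[tuple, list] = {}
        for i, t in enumerate(scope.triples):
            if scope.consumed[i] or t.pred != voc.RDF_TYPE:
                continue
            if t.obj != voc.OWL_AXIOM:
                continue
            scope.consume(i)
            b = t.subj
            parts = {}
            for role in (voc.OWL_ANNOTATED_SOURCE, voc.OWL_ANNOTATED_PROPERTY,
                         voc.OWL_ANNOTATED_TARGET):
                hits = scope.sp(b, role)
                if len(hits) != 1:
                    raise MappingError(
                        "structure",
                        f"owl:Axiom node {store.node_str(b)} lacks a unique "
                        f"{store.node_str(role)}",
                    )
                scope.consume(hits[0])
                parts[role] = scope.triples[hits[0]].obj
            key = (
                int(parts[voc.OWL_ANNOTATED_SOURCE]),
                int(parts[voc.OWL_ANNOTATED_PROPERTY]),
                int(parts[voc.OWL_ANNOTATED_TARGET]),
            )
            anns = []
            for j in scope.subject_triples(b):
                tj = scope.triples[j]
                if not self._is_annotation_property(tj.pred):
                    raise MappingError(
                        "structure",
                        f"non-annotation triple on owl:Axiom node "
                        f"{store.node_str(b)}",
                    )
                scope.consume(j)
                anns.append((tj.pred, tj.obj))
            out.setdefault(key, []).extend(anns)
        return out

    def _is_annotation_property(self, pred: NodeId) -> bool:
        return self.decls.has(pred, "AnnotationProperty")

    # -- main ----------------------------------------------------------------

    def run(self) -> list[Axiom]:
        store, scope = self.store, self.scope
        check_standard_terms(store, scope.triples)
        self.decls = collect_declarations(store, scope=scope)
        self._emit_declarations()
        self._map_headers()
        reified = self._collect_reified()

        for i, t in enumerate(scope.triples):
            if scope.consumed[i]:
                continue
            axiom = self._trigger(i, t)
            if axiom is not None:
                self.axioms.append(axiom)
                self.by_trigger[(int(t.subj), int(t.pred), int(t.obj))] = axiom

        leftovers = scope.leftovers()
        if leftovers:
            t = leftovers[0]
            raise MappingError(
                "structure",
                f"{len(leftovers)} unconsumed triple(s); first: "
                f"{store.node_str(t.subj)} {store.node_str(t.pred)} "
                f"{store.node_str(t.obj)}",
            )

        for key, anns in reified.items():
            axiom = self.by_trigger.get(key)
            if axiom is None:
                s, p, o = (NodeId(k) for k in key)
                raise MappingError(
                    "structure",
                    "reified annotation without a matching axiom: "
                    f"{store.node_str(s)} {store.node_str(p)} "
                    f"{store.node_str(o)}",
                )
            axiom.annotations = tuple(
                sorted(anns, key=lambda a: (int(a[0]), int(a[1])))
            )
        return self.axioms

    def _emit_declarations(self) -> None:
        seen = set()
        for i, t in enumerate(self.scope.triples):
            if t.pred != voc.RDF_TYPE:
                continue
            kind = DECLARATION_KINDS.get(t.obj)
            if kind is None or not isinstance(self.store[t.subj], NodeIri):
                continue
            if (int(t.subj), kind) in seen:
                continue
            seen.add((int(t.subj), kind))
            axiom = Axiom("Declaration", (kind, t.subj))
            self.axioms.append(axiom)
            self.by_trigger[(int(t.subj), int(t.pred), int(t.obj))] = axiom

    def _map_headers(self) -> None:
        store, scope = self.store, self.scope
        for i, t in enumerate(scope.triples):
            if scope.consumed[i] or t.pred != voc.RDF_TYPE:
                continue
            if t.obj != voc.OWL_ONTOLOGY:
                continue
            scope.consume(i)
            subj = t.subj
            version = None
            imports = []
            anns = []
            for j in scope.subject_triples(subj):
                tj = scope.triples[j]
                if tj.pred == voc.OWL_VERSION_IRI:
                    version = tj.obj
                    scope.consume(j)
                elif tj.pred == voc.OWL_IMPORTS:
                    imports.append(tj.obj)
                    scope.consume(j)
                elif self._is_annotation_property(tj.pred):
                    anns.append((tj.pred, tj.obj))
                    scope.consume(j)
            iri = subj if isinstance(store[subj], NodeIri) else None
            self.axioms.append(
                Axiom(
                    "Ontology",
                    (iri, version, tuple(imports)),
                    tuple(anns),
                )
            )

    def _trigger(self, i: int, t: Triple) -> Optional[Axiom]:
        store, scope, decls = self.store, self.scope, self.decls
        s, p, o = t.subj, t.pred, t.obj

        # expression structure anchored at a blank node is consumed when the
        # axiom referencing it is parsed; defer (leftovers are caught last)
        if p in _EXPRESSION_PREDICATES and isinstance(store[s], NodeBlank):
            return None

        if p == voc.RDFS_SUBCLASSOF:
            scope.consume(i)
            return Axiom(
                "SubClassOf",
                (self.class_expression(s), self.class_expression(o)),
            )
        if p == voc.OWL_EQUIVALENT_CLASS:
            scope.consume(i)
            return Axiom(
                "EquivalentClasses",
                (self.class_expression(s), self.class_expression(o)),
            )
        if p == voc.OWL_DISJOINT_WITH:
            scope.consume(i)
            return Axiom(
                "DisjointClasses",
                (self.class_expression(s), self.class_expression(o)),
            )
        if p == voc.RDFS_SUBPROPERTYOF:
            scope.consume(i)
            return self._sub_property(s, o)
        if p in (voc.RDFS_DOMAIN, voc.RDFS_RANGE):
            scope.consume(i)
            return self._domain_range(s, p, o)
        if p == voc.RDF_TYPE:
            return self._type_trigger(i, s, o)

        if decls.has(p, "ObjectProperty"):
            if isinstance(store[o], NodeLiteral):
                raise MappingError(
                    "structure",
                    f"object property {store.node_str(p)} asserted with a "
                    "literal object",
                )
            scope.consume(i)
            return Axiom("ObjectPropertyAssertion", (p, s, o))
        if decls.has(p, "DataProperty"):
            if not isinstance(store[o], NodeLiteral):
                raise MappingError(
                    "structure",
                    f"data property {store.node_str(p)} asserted with a "
                    "non-literal object",
                )
            scope.consume(i)
            return Axiom("DataPropertyAssertion", (p, s, o))
        if self._is_annotation_property(p):
            scope.consume(i)
            return Axiom("AnnotationAssertion", (p, s, o))

        node = store[p]
        if isinstance(node, NodeIri):
            if p < voc.VOCABULARY_SIZE:
                raise MappingError(
                    "unsupported",
                    f"unsupported construct: predicate {store.node_str(p)}",
                )
            raise MappingError(
                "undeclared",
                f"undeclared predicate {store.node_str(p)}",
            )
        raise MappingError(
            "structure",
            f"non-IRI predicate {store.node_str(p)}",
        )

    def _sub_property(self, s: NodeId, o: NodeId) -> Axiom:
        decls = self.decls
        for kind, name in (
            ("ObjectProperty", "SubObjectPropertyOf"),
            ("DataProperty", "SubDataPropertyOf"),
            ("AnnotationProperty", "SubAnnotationPropertyOf"),
        ):
            if decls.has(s, kind):
                if not decls.has(o, kind):
                    raise MappingError(
                        "undeclared",
                        f"rdfs:subPropertyOf relates {kind} "
                        f"{self.store.node_str(s)} to undeclared "
                        f"{self.store.node_str(o)}",
                    )
                return Axiom(name, (s, o))
        raise MappingError(
            "undeclared",
            f"rdfs:subPropertyOf on undeclared property "
            f"{self.store.node_str(s)}",
        )

    def _domain_range(self, s: NodeId, p: NodeId, o: NodeId) -> Axiom:
        decls = self.decls
        which = "Domain" if p == voc.RDFS_DOMAIN else "Range"
        if decls.has(s, "ObjectProperty"):
            return Axiom(
                f"ObjectProperty{which}", (s, self.class_expression(o))
            )
        if decls.has(s, "DataProperty"):
            if which == "Domain":
                return Axiom(
                    "DataPropertyDomain", (s, self.class_expression(o))
                )
            return Axiom("DataPropertyRange", (s, self._datatype(o)))
        if decls.has(s, "AnnotationProperty"):
            return Axiom(f"AnnotationProperty{which}", (s, o))
        raise MappingError(
            "undeclared",
            f"rdfs:{which.lower()} on undeclared property "
            f"{self.store.node_str(s)}",
        )

    def _type_trigger(self, i: int, s: NodeId, o: NodeId) -> Optional[Axiom]:
        store, scope, decls = self.store, self.scope, self.decls
        characteristic = _CHARACTERISTICS.get(o)
        if characteristic is not None:
            scope.consume(i)
            if decls.has(s, "ObjectProperty"):
                return Axiom(
                    f"{characteristic}ObjectProperty", (s,)
                )
            if characteristic == "Functional" and decls.has(s, "DataProperty"):
                return Axiom("FunctionalDataProperty", (s,))
            raise MappingError(
                "undeclared",
                f"property characteristic on undeclared property "
                f"{store.node_str(s)}",
            )
        obj_node = store[o]
        if isinstance(obj_node, NodeIri) and o < voc.VOCABULARY_SIZE:
            frag = voc.STANDARD_TERMS[int(o)][1]
            if frag in _UNSUPPORTED_TYPE_OBJECTS:
                raise MappingError(
                    "unsupported",
                    f"unsupported construct: rdf:type "
                    f"{store.node_str(o)}",
                )
        # a blank node typed owl:Class / owl:Restriction anchors a class
        # expression; its triples are consumed when the expression that
        # references it is parsed (leftovers are caught at the end)
        if isinstance(store[s], NodeBlank) and o in (
            voc.OWL_CLASS, voc.OWL_RESTRICTION
        ):
            return None
        # class assertion: object is a declared class or a blank expression
        if isinstance(obj_node, NodeIri) and not decls.has(o, "Class"):
            raise MappingError(
                "undeclared",
                f"rdf:type object {store.node_str(o)} is not a declared "
                "class",
            )
        if isinstance(store[s], NodeLiteral):
            raise MappingError(
                "structure", "literal subject in a class assertion"
            )
        scope.consume(i)
        return Axiom("ClassAssertion", (self.class_expression(o), s))


def map_axioms(
    store: TripleStore,
    doc: Optional[DocId] = None,
    triples: Optional[Sequence[Triple]] = None,
) -> list[Axiom]:
    """Translate the store's triples (optionally one document's, or an
    explicit subset) into OWL 2 axioms.

    Strict: any violation raises :class:`MappingError` and no partial
    result is observable.  Every triple in scope is consumed exactly once.
    """
    scope = _scope_for(store, doc, triples)
    return _Mapper(store, scope).run()


# --------------------------------------------------------------------------
# functional-style syntax serialization
# --------------------------------------------------------------------------

_NCNAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")

_FIXED_PREFIXES = {
    voc.RDF: "rdf",
    voc.RDFS: "rdfs",
    voc.OWL: "owl",
    voc.XSD: "xsd",
}

_KIND_ORDER = [
    "Ontology", "Declaration", "SubClassOf", "EquivalentClasses",
    "DisjointClasses", "SubObjectPropertyOf", "SubDataPropertyOf",
    "SubAnnotationPropertyOf", "ObjectPropertyDomain", "ObjectPropertyRange",
    "DataPropertyDomain", "DataPropertyRange", "AnnotationPropertyDomain",
    "AnnotationPropertyRange", "FunctionalObjectProperty",
    "InverseFunctionalObjectProperty", "TransitiveObjectProperty",
    "SymmetricObjectProperty", "FunctionalDataProperty", "ClassAssertion",
    "ObjectPropertyAssertion", "DataPropertyAssertion",
    "AnnotationAssertion",
]


class _PrefixMap:
    def __init__(self, store: TripleStore):
        self.store = store
        self.prefixes: dict[str, str] = {}
        self._used: set[str] = set(_FIXED_PREFIXES.values())

    def entity(self, node_id: NodeId) -> str:
        node = self.store[node_id]
        ns_iri = self.store[node.ns] if isinstance(node, NodeIri) else None
        if ns_iri is None:
            raise MappingError(
                "structure",
                f"cannot serialize {self.store.node_str(node_id)} as an "
                "entity",
            )
        iri = self.store.iri_str(node_id)
        if not _NCNAME_RE.match(node.fragment):
            return f"<{iri}>"
        prefix = self._prefix_for(ns_iri)
        return f"{prefix}:{node.fragment}"

    def _prefix_for(self, ns_iri: str) -> str:
        fixed = _FIXED_PREFIXES.get(ns_iri)
        if fixed is not None:
            self.prefixes.setdefault(ns_iri, fixed)
            return fixed
        existing = self.prefixes.get(ns_iri)
        if existing is not None:
            return existing
        stem = re.sub(r"[^A-Za-z0-9]", "", ns_iri.rstrip("#/").rsplit("/", 1)[-1])
        stem = (stem or "ns")[:12]
        if not stem[0].isalpha():
            stem = "ns" + stem
        candidate, k = stem, 1
        while candidate in self._used:
            k += 1
            candidate = f"{stem}{k}"
        self._used.add(candidate)
        self.prefixes[ns_iri] = candidate
        return candidate


def _render_term(pm: _PrefixMap, node_id: NodeId) -> str:
    store = pm.store
    node = store[node_id]
    if isinstance(node, NodeIri):
        return pm.entity(node_id)
    if isinstance(node, NodeBlank):
        return f"_:d{int(node.doc)}b{node.ordinal}"
    lit: NodeLiteral = node
    body = '"' + lit.lexical.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if lit.language:
        return f"{body}@{lit.language}"
    if lit.datatype == voc.XSD_STRING:
        return body
    return f"{body}^^{pm.entity(lit.datatype)}"


def _render_class_expr(pm: _PrefixMap, expr: ClassExpr) -> str:
    if expr.kind == "named":
        return pm.entity(expr.node)
    if expr.kind in ("and", "or"):
        name = "ObjectIntersectionOf" if expr.kind == "and" else "ObjectUnionOf"
        inner = " ".join(
            sorted(_render_class_expr(pm, p) for p in expr.parts)
        )
        return f"{name}({inner})"
    if expr.kind == "not":
        return f"ObjectComplementOf({_render_class_expr(pm, expr.parts[0])})"
    if expr.kind == "oneOf":
        inner = " ".join(sorted(_render_term(pm, m) for m in expr.parts))
        return f"ObjectOneOf({inner})"
    prefix = "Data" if expr.data else "Object"
    prop = pm.entity(expr.prop)
    if expr.kind in ("some", "only"):
        name = "SomeValuesFrom" if expr.kind == "some" else "AllValuesFrom"
        filler = (
            pm.entity(expr.filler) if expr.data
            else _render_class_expr(pm, expr.filler)
        )
        return f"{prefix}{name}({prop} {filler})"
    if expr.kind == "value":
        return f"{prefix}HasValue({prop} {_render_term(pm, expr.filler)})"
    name = {"min": "MinCardinality", "max": "MaxCardinality",
            "exactly": "ExactCardinality"}[expr.kind]
    parts = [str(expr.n), prop]
    if expr.filler is not None:
        parts.append(
            pm.entity(expr.filler) if expr.data
            else _render_class_expr(pm, expr.filler)
        )
    return f"{prefix}{name}({' '.join(parts)})"


def _render_operand(pm: _PrefixMap, op) -> str:
    if isinstance(op, ClassExpr):
        return _render_class_expr(pm, op)
    if isinstance(op, NodeId):
        return _render_term(pm, op)
    return str(op)


_SYMMETRIC_KINDS = {"EquivalentClasses", "DisjointClasses"}


def render_axiom(pm: _PrefixMap, axiom: Axiom) -> str:
    """One axiom in functional-style syntax (without trailing newline)."""
    anns = "".join(
        f"Annotation({pm.entity(p)} {_render_term(pm, v)}) "
        for p, v in axiom.annotations
    )
    if axiom.kind == "Ontology":
        raise ValueError("the ontology header is rendered by the serializer")
    if axiom.kind == "Declaration":
        entity_kind, node = axiom.operands
        keyword = "DataProperty" if entity_kind == "DataProperty" else entity_kind
        return f"Declaration({anns}{keyword}({pm.entity(node)}))"
    rendered = [_render_operand(pm, op) for op in axiom.operands]
    if axiom.kind in _SYMMETRIC_KINDS:
        rendered = sorted(rendered)
    return f"{axiom.kind}({anns}{' '.join(rendered)})"


def serialize_functional(axioms: Sequence[Axiom], store: TripleStore) -> str:
    """Serialize axioms as an OWL 2 functional-style syntax document.

    Output is deterministic: declarations first, remaining axioms sorted
    by kind then by rendered operands; prefixes are declared for every
    namespace used.
    """
    pm = _PrefixMap(store)
    for ns in _FIXED_PREFIXES:
        pm._prefix_for(ns)
    header = next((a for a in axioms if a.kind == "Ontology"), None)
    body: list[tuple[int, str]] = []
    for axiom in axioms:
        if axiom.kind == "Ontology":
            continue
        rank = (
            _KIND_ORDER.index(axiom.kind)
            if axiom.kind in _KIND_ORDER else len(_KIND_ORDER)
        )
        body.append((rank, render_axiom(pm, axiom)))
    body.sort()

    header_lines: list[str] = []
    ontology_iris = ""
    if header is not None:
        iri, version, imports = header.operands
        bits = []
        if iri is not None:
            bits.append(f"<{store.iri_str(iri)}>")
        if version is not None:
            bits.append(f"<{store.iri_str(version)}>")
        ontology_iris = (" " + " ".join(bits)) if bits else ""
        for imp in imports:
            header_lines.append(f"Import(<{store.iri_str(imp)}>)")
        for p, v in header.annotations:
            header_lines.append(
                f"Annotation({pm.entity(p)} {_render_term(pm, v)})"
            )

    lines = [
        f"Prefix({name}:=<{ns}>)"
        for ns, name in sorted(pm.prefixes.items(), key=lambda kv: kv[1])
    ]
    lines.append(f"Ontology({ontology_iris.strip()}" if ontology_iris else "Ontology(")
    lines.extend(header_lines)
    lines.extend(text for _rank, text in body)
    lines.append(")")
    return "\n".join(lines) + "\n"
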
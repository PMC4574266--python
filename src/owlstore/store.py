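"""In-memory RDF triple store with interned terms and configurable indices.

The :class:`TripleStore` is the central container: it interns namespace
prefixes, IRI/literal/blank terms, and document descriptors behind small
integer IDs, and stores generalized RDF quads ``(subject, predicate,
object, document)`` in one or more sorted indices.

An index bins triples by one term and keeps each bin sorted by the three
remaining terms; ``find_triples`` picks, per query pattern, the index whose
bin key is constrained and whose sort order covers the most additionally
constrained terms as a prefix (resolved by binary search), falling back to
a full scan when no index applies.  The default configuration bins by
subject (sorted predicate, object, document) and by object (sorted
predicate, subject, document).

All mutating operations require exclusive access; read-only operations may
be freely interleaved.  No locking is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

from . import vocabulary as voc
from .ids import DocId, NodeId, NsId
from .nodes import (
    DocMeta,
    Node,
    NodeBlank,
    NodeIri,
    NodeLiteral,
    is_absolute_iri,
    parse_literal_value,
    split_iri,
)


class Triple(NamedTuple):
    """A generalized RDF triple plus its source document.

    No positional type restriction is enforced: a literal subject or a
    blank predicate is representable (though never produced by parsing).
    """

    subj: NodeId
    pred: NodeId
    obj: NodeId
    doc: DocId


class TriplePattern(NamedTuple):
    """A query pattern; ``None`` in a position is a wildcard."""

    subj: Optional[NodeId] = None
    pred: Optional[NodeId] = None
    obj: Optional[NodeId] = None
    doc: Optional[DocId] = None


_FIELD_POS = {"s": 0, "p": 1, "o": 2, "d": 3}
_FIELDS = ("s", "p", "o", "d")


class IndexConfigError(ValueError):
    """Invalid or duplicate triple-index layout."""


@dataclass(frozen=True)
class IndexSpec:
    """Layout of one triple index: bin key plus sort order of the rest."""

    bin_key: str
    sort_order: tuple[str, str, str]

    def __post_init__(self) -> None:
        if self.bin_key not in _FIELD_POS:
            raise IndexConfigError(f"unknown bin key {self.bin_key!r}")
        if sorted((self.bin_key, *self.sort_order)) != sorted(_FIELDS):
            raise IndexConfigError(
                f"sort order {self.sort_order!r} must be a permutation of the "
                f"three keys other than {self.bin_key!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "IndexSpec":
        """Parse a compact layout string such as ``"s:pod"``."""
        try:
            bin_key, order = text.split(":")
        except ValueError:
            raise IndexConfigError(f"bad index layout {text!r}") from None
        if len(order) != 3:
            raise IndexConfigError(f"bad index layout {text!r}")
        return cls(bin_key, tuple(order))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return f"{self.bin_key}:{''.join(self.sort_order)}"


#: The default two-index configuration.
DEFAULT_INDEX_CONFIG: tuple[str, ...] = ("s:pod", "o:psd")


class ComparisonCounter:
    """Counts element (ID) comparisons performed while answering queries."""

    __slots__ = ("comparisons",)

    def __init__(self) -> None:
        self.comparisons = 0


class _TripleIndex:
    """Triples binned by one term, each bin sorted by the remaining terms."""

    __slots__ = ("spec", "bins", "_bin_pos", "_sort_pos")

    def __init__(self, spec: IndexSpec):
        self.spec = spec
        self.bins: dict[int, list[Triple]] = {}
        self._bin_pos = _FIELD_POS[spec.bin_key]
        self._sort_pos = tuple(_FIELD_POS[f] for f in spec.sort_order)

    def sort_key(self, t: Triple) -> tuple[int, int, int]:
        p = self._sort_pos
        return (t[p[0]], t[p[1]], t[p[2]])

    def insert(self, t: Triple) -> None:
        bin_ = self.bins.setdefault(t[self._bin_pos], [])
        key = self.sort_key(t)
        lo, hi = 0, len(bin_)
        while lo < hi:
            mid = (lo + hi) // 2
            if self.sort_key(bin_[mid]) < key:
                lo = mid + 1
            else:
                hi = mid
        bin_.insert(lo, t)

    def remove(self, t: Triple) -> None:
        bin_ = self.bins.get(t[self._bin_pos])
        if bin_ is not None:
            bin_.remove(t)
            if not bin_:
                del self.bins[t[self._bin_pos]]


class TripleStore:
    """Container for namespaces, terms, documents, and indexed triples.

    Parameters
    ----------
    index_config
        Iterable of index layouts, each an :class:`IndexSpec` or a compact
        string like ``"s:pod"`` (bin key ``:`` sort order).  Defaults to
        the two-index configuration ``("s:pod", "o:psd")``.
    """

    def __init__(self, index_config: Optional[Iterable] = None):
        if index_config is None:
            index_config = DEFAULT_INDEX_CONFIG
        specs = [
            s if isinstance(s, IndexSpec) else IndexSpec.parse(s)
            for s in index_config
        ]
        if not specs:
            raise IndexConfigError("at least one triple index is required")
        if len(set(specs)) != len(specs):
            raise IndexConfigError("duplicate index layout")
        self._indices = [_TripleIndex(s) for s in specs]

        self._namespaces: list[str] = []
        self._ns_map: dict[str, NsId] = {}
        self._nodes: list[Node] = []
        self._node_map: dict[tuple, NodeId] = {}
        self._docs: list[DocMeta] = []
        self._doc_by_path: dict[str, DocId] = {}
        self._blank_labels: dict[tuple[int, str], NodeId] = {}
        self._blank_counts: dict[int, int] = {}
        self._triples: list[Triple] = []
        self._triple_set: set[Triple] = set()

        for ns in voc.STANDARD_NAMESPACES:
            self._intern_ns(ns)
        for ns_id, frag in voc.STANDARD_TERMS:
            self._intern_iri_parts(NsId(ns_id), frag)

    # --- namespaces --------------------------------------------------------

    def _intern_ns(self, prefix: str) -> NsId:
        existing = self._ns_map.get(prefix)
        if existing is not None:
            return existing
        ns_id = NsId(len(self._namespaces))
        self._namespaces.append(prefix)
        self._ns_map[prefix] = ns_id
        return ns_id

    @property
    def n_namespaces(self) -> int:
        return len(self._namespaces)

    # --- nodes -------------------------------------------------------------

    def _intern_iri_parts(self, ns: NsId, fragment: str) -> NodeId:
        key = ("i", int(ns), fragment)
        existing = self._node_map.get(key)
        if existing is not None:
            return existing
        node_id = NodeId(len(self._nodes))
        self._nodes.append(NodeIri(node_id, ns, fragment))
        self._node_map[key] = node_id
        return node_id

    def intern_iri(self, iri: str) -> NodeId:
        """Intern an absolute IRI, returning its (stable) NodeId."""
        if not iri or not is_absolute_iri(iri):
            raise ValueError(f"not an absolute IRI: {iri!r}")
        prefix, fragment = split_iri(iri)
        return self._intern_iri_parts(self._intern_ns(prefix), fragment)

    def lookup_iri(self, iri: str) -> Optional[NodeId]:
        """Return the NodeId of an already-interned IRI, or None."""
        prefix, fragment = split_iri(iri)
        ns = self._ns_map.get(prefix)
        if ns is None:
            return None
        return self._node_map.get(("i", int(ns), fragment))

    def intern_literal(
        self,
        lexical: str,
        datatype: Optional[NodeId] = None,
        language: str = "",
    ) -> NodeId:
        """Intern a typed literal; value-equal literals share a NodeId.

        The lexical form is parsed according to the datatype (boolean,
        integer family, decimal, float/double; anything else is kept as a
        string).  ``language`` may be non-empty only for plain/string
        datatypes.  With no datatype given, the literal is typed
        ``xsd:string``, or ``rdf:langString`` when a language is present.
        """
        if datatype is None:
            datatype = voc.RDF_LANG_STRING if language else voc.XSD_STRING
        dt_node = self[datatype]
        if not isinstance(dt_node, NodeIri):
            raise ValueError("literal datatype must be an IRI node")
        if language and datatype not in voc.STRINGY_DATATYPES:
            raise ValueError(
                "language tag allowed only on plain/string literals"
            )
        dt_iri = self.iri_str(datatype)
        value, canon = parse_literal_value(lexical, dt_iri)
        key = ("l", int(datatype), canon, language)
        existing = self._node_map.get(key)
        if existing is not None:
            return existing
        node_id = NodeId(len(self._nodes))
        self._nodes.append(
            NodeLiteral(node_id, datatype, value, language, lexical)
        )
        self._node_map[key] = node_id
        return node_id

    def make_blank(self, doc: DocId, label: Optional[str] = None) -> NodeId:
        """Create or retrieve a document-scoped blank node.

        The same ``(doc, label)`` pair always yields the same NodeId; equal
        labels under different documents yield distinct NodeIds.  With no
        label a fresh blank is created on every call.
        """
        self._check_doc(doc)
        if label is not None:
            existing = self._blank_labels.get((int(doc), label))
            if existing is not None:
                return existing
        ordinal = self._blank_counts.get(int(doc), 0)
        node_id = NodeId(len(self._nodes))
        self._nodes.append(NodeBlank(node_id, doc, ordinal))
        self._blank_counts[int(doc)] = ordinal + 1
        if label is not None:
            self._blank_labels[(int(doc), label)] = node_id
        return node_id

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def term_counts(self) -> dict[str, int]:
        """Counts of document-derived IRI, literal, and blank terms.

        The pre-interned standard vocabulary is excluded from the IRI
        count so the numbers reflect loaded content.
        """
        counts = {"iri": 0, "literal": 0, "blank": 0}
        for node in self._nodes:
            if isinstance(node, NodeIri):
                counts["iri"] += 1
            elif isinstance(node, NodeLiteral):
                counts["literal"] += 1
            else:
                counts["blank"] += 1
        counts["iri"] -= voc.VOCABULARY_SIZE
        return counts

    # --- documents ---------------------------------------------------------

    def add_doc(
        self,
        path: str,
        ontology_iri: Optional[NodeId] = None,
        version_iri: Optional[NodeId] = None,
        imports: Sequence[NodeId] = (),
    ) -> DocId:
        """Register an ontology document descriptor; path must be unique."""
        if path in self._doc_by_path:
            raise ValueError(f"document path already registered: {path!r}")
        doc_id = DocId(len(self._docs))
        self._docs.append(
            DocMeta(doc_id, path, ontology_iri, version_iri, tuple(imports))
        )
        self._doc_by_path[path] = doc_id
        return doc_id

    def doc_by_path(self, path: str) -> Optional[DocId]:
        return self._doc_by_path.get(path)

    @property
    def docs(self) -> Sequence[DocMeta]:
        return tuple(self._docs)

    @property
    def n_docs(self) -> int:
        return len(self._docs)

    def _check_doc(self, doc: DocId) -> None:
        if not isinstance(doc, int) or not 0 <= doc < len(self._docs):
            raise LookupError(f"unknown document id {doc!r}")

    # --- object retrieval ---------------------------------------------------

    def __getitem__(self, obj_id):
        """Retrieve the object behind an ID (inverse of interning)."""
        if isinstance(obj_id, NsId):
            if 0 <= obj_id < len(self._namespaces):
                return self._namespaces[obj_id]
            raise LookupError(f"unknown namespace id {obj_id!r}")
        if isinstance(obj_id, DocId):
            self._check_doc(obj_id)
            return self._docs[obj_id]
        if isinstance(obj_id, NodeId):
            if 0 <= obj_id < len(self._nodes):
                return self._nodes[obj_id]
            raise LookupError(f"unknown node id {obj_id!r}")
        raise LookupError(f"not a store-issued id: {obj_id!r}")

    def iri_str(self, node_id: NodeId) -> str:
        """Reconstruct the full IRI string of an IRI node."""
        node = self[node_id]
        if not isinstance(node, NodeIri):
            raise LookupError(f"node {node_id!r} is not an IRI node")
        return self._namespaces[node.ns] + node.fragment

    def node_str(self, node_id: NodeId) -> str:
        """Human-readable rendering of any node (for reports and the CLI)."""
        node = self[node_id]
        if isinstance(node, NodeIri):
            return "<" + self.iri_str(node_id) + ">"
        if isinstance(node, NodeBlank):
            return f"_:d{int(node.doc)}b{node.ordinal}"
        lit: NodeLiteral = node
        out = '"' + lit.lexical.replace("\\", "\\\\").replace('"', '\\"') + '"'
        if lit.language:
            return out + "@" + lit.language
        if lit.datatype != voc.XSD_STRING:
            return out + "^^<" + self.iri_str(lit.datatype) + ">"
        return out

    # --- triples -----------------------------------------------------------

    def add_triple(
        self, subj: NodeId, pred: NodeId, obj: NodeId, doc: DocId
    ) -> None:
        """Insert a triple into every index; duplicates are no-ops."""
        for nid in (subj, pred, obj):
            if not isinstance(nid, int) or not 0 <= nid < len(self._nodes):
                raise LookupError(f"unresolvable node id {nid!r}")
        self._check_doc(doc)
        t = Triple(subj, pred, obj, doc)
        if t in self._triple_set:
            return
        self._triple_set.add(t)
        self._triples.append(t)
        for index in self._indices:
            index.insert(t)

    @property
    def n_triples(self) -> int:
        return len(self._triples)

    @property
    def triples(self) -> Sequence[Triple]:
        return tuple(self._triples)

    @property
    def index_specs(self) -> tuple[IndexSpec, ...]:
        return tuple(ix.spec for ix in self._indices)

    def find_triples(
        self,
        pattern: Optional[TriplePattern] = None,
        *,
        subj: Optional[NodeId] = None,
        pred: Optional[NodeId] = None,
        obj: Optional[NodeId] = None,
        doc: Optional[DocId] = None,
        counter: Optional[ComparisonCounter] = None,
    ) -> Iterator[Triple]:
        """Lazily iterate over triples matching the pattern.

        Positions left as ``None`` are wildcards; unknown IDs simply match
        nothing.  The most suitable index is selected automatically; when
        no index bins by a constrained term, a full scan is used.
        """
        if pattern is None:
            pattern = TriplePattern(subj, pred, obj, doc)
        constrained = {
            f: v
            for f, v in zip(_FIELDS, pattern)
            if v is not None
        }
        index, prefix_len = self._select_index(constrained)
        if index is None:
            return self._scan(self._triples, constrained, counter)
        bin_ = index.bins.get(int(constrained[index.spec.bin_key]), [])
        prefix = index.spec.sort_order[:prefix_len]
        target = tuple(int(constrained[f]) for f in prefix)
        lo = self._bisect(bin_, index, target, counter, right=False)
        hi = self._bisect(bin_, index, target, counter, right=True)
        residual = {
            f: v
            for f, v in constrained.items()
            if f != index.spec.bin_key and f not in prefix
        }
        return self._scan(bin_[lo:hi], residual, counter)

    def contains(self, pattern: TriplePattern) -> bool:
        """True if at least one triple matches the pattern."""
        return next(iter(self.find_triples(pattern)), None) is not None

    def _select_index(self, constrained: dict):
        best = None
        best_score = -1
        for index in self._indices:
            if index.spec.bin_key not in constrained:
                continue
            score = 0
            for f in index.spec.sort_order:
                if f in constrained:
                    score += 1
                else:
                    break
            if score > best_score:
                best, best_score = index, score
        if best is None:
            return None, 0
        return best, best_score

    @staticmethod
    def _scan(
        triples: Sequence[Triple],
        constrained: dict,
        counter: Optional[ComparisonCounter],
    ) -> Iterator[Triple]:
        checks = [(_FIELD_POS[f], int(v)) for f, v in constrained.items()]
        if counter is None:
            for t in triples:
                if all(t[pos] == v for pos, v in checks):
                    yield t
        else:
            for t in triples:
                ok = True
                for pos, v in checks:
                    counter.comparisons += 1
                    if t[pos] != v:
                        ok = False
                        break
                if ok:
                    yield t

    @staticmethod
    def _bisect(
        bin_: list,
        index: _TripleIndex,
        target: tuple,
        counter: Optional[ComparisonCounter],
        right: bool,
    ) -> int:
        k = len(target)
        lo, hi = 0, len(bin_)
        while lo < hi:
            mid = (lo + hi) // 2
            key = index.sort_key(bin_[mid])[:k]
            if counter is not None:
                # count elementwise comparisons up to the deciding position
                cmp_cost = 1
                for a, b in zip(key, target):
                    if a != b:
                        break
                    cmp_cost += 1
                counter.comparisons += min(cmp_cost, k) if k else 0
            if (key < target) if not right else (key <= target):
                lo = mid + 1
            else:
                hi = mid
        return lo

    # --- transactions -------------------------------------------------------

    def checkpoint(self) -> tuple[int, int, int, int]:
        """Snapshot of store sizes, for :meth:`rollback`."""
        return (
            len(self._namespaces),
            len(self._nodes),
            len(self._docs),
            len(self._triples),
        )

    def rollback(self, checkpoint: tuple[int, int, int, int]) -> None:
        """Undo every mutation since ``checkpoint`` was taken."""
        n_ns, n_nodes, n_docs, n_triples = checkpoint
        for t in self._triples[n_triples:]:
            self._triple_set.discard(t)
            for index in self._indices:
                index.remove(t)
        del self._triples[n_triples:]
        for path in [
            p for p, d in self._doc_by_path.items() if d >= n_docs
        ]:
            del self._doc_by_path[path]
        for key in [k for k, d in self._blank_labels.items() if k[0] >= n_docs]:
            del self._blank_labels[key]
        for d in [d for d in self._blank_counts if d >= n_docs]:
            del self._blank_counts[d]
        del self._docs[n_docs:]
        for key in [k for k, nid in self._node_map.items() if nid >= n_nodes]:
            del self._node_map[key]
        del self._nodes[n_nodes:]
        for prefix in [p for p, ns in self._ns_map.items() if ns >= n_ns]:
            del self._ns_map[prefix]
        del self._namespaces[n_ns:]

    # --- reconfiguration -----------------------------------------------------

    def reindexed(self, index_config: Iterable) -> "TripleStore":
        """A store with identical contents and IDs but different indices.

        Term tables are shared copies; triples are re-inserted into the new
        index layouts.  Used by the index-configuration study.
        """
        other = TripleStore.__new__(TripleStore)
        specs = [
            s if isinstance(s, IndexSpec) else IndexSpec.parse(s)
            for s in index_config
        ]
        if not specs:
            raise IndexConfigError("at least one triple index is required")
        if len(set(specs)) != len(specs):
            raise IndexConfigError("duplicate index layout")
        other._indices = [_TripleIndex(s) for s in specs]
        other._namespaces = list(self._namespaces)
        other._ns_map = dict(self._ns_map)
        other._nodes = list(self._nodes)
        other._node_map = dict(self._node_map)
        other._docs = list(self._docs)
        other._doc_by_path = dict(self._doc_by_path)
        other._blank_labels = dict(self._blank_labels)
        other._blank_counts = dict(self._blank_counts)
        other._triples = list(self._triples)
        other._triple_set = set(self._triple_set)
        for t in other._triples:
            for index in other._indices:
                index.insert(t)
        return other
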
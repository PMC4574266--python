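"""Transactional loading of RDF/XML ontology documents into a store.

A document is parsed and validated completely — XML well-formedness,
RDF/XML structure, literal lexical forms, and the OWL document header —
before the store is touched, so any failure leaves the store exactly as it
was.  When a :class:`~owlstore.catalog.Catalog` is supplied, the
``owl:imports`` closure is resolved against it and loaded depth-first,
each document at most once (cycle-safe); a failure anywhere in the closure
rolls the whole top-level load back.

Documents are never fetched from the Internet: a non-file import IRI is
resolvable only through the catalog.
"""

from __future__ import annotations

import logging
import os
from typing import BinaryIO, Optional, Union

from . import vocabulary as voc
from .catalog import Catalog, ResolutionError
from .ids import DocId
from .nodes import LiteralParseError, parse_literal_value
from .rdfxml import (
    BlankRef,
    IriRef,
    LiteralRef,
    ParseError,
    RawStatement,
    parse_rdfxml,
)
from .store import TripleStore

logger = logging.getLogger(__name__)

_RDF_TYPE = voc.RDF + "type"
_OWL_ONTOLOGY = voc.OWL + "Ontology"
_OWL_VERSION_IRI = voc.OWL + "versionIRI"
_OWL_IMPORTS = voc.OWL + "imports"


class LoadError(Exception):
    """Failure at any stage of document loading.

    ``stage`` is one of ``file``, ``xml``, ``rdf``, ``owl``.  Raising a
    LoadError guarantees the target store is unchanged.
    """

    def __init__(
        self,
        stage: str,
        message: str,
        path: Optional[str] = None,
        line: Optional[int] = None,
    ):
        self.stage = stage
        self.message = message
        self.path = path
        self.line = line
        where = ""
        if path:
            where += f" [{path}" + (f":{line}" if line else "") + "]"
        elif line:
            where += f" [line {line}]"
        super().__init__(f"{stage} error: {message}{where}")


def file_iri(path: Union[str, os.PathLike]) -> str:
    """The ``file://`` IRI of an absolute filesystem path."""
    return "file://" + os.path.abspath(os.fspath(path))


def _validate_header(
    statements: list[RawStatement], path: Optional[str]
) -> tuple[Optional[str], Optional[str], list[str]]:
    """Extract (ontology IRI, version IRI, imports); enforce one header."""
    headers = [
        st for st in statements
        if st.pred == _RDF_TYPE
        and isinstance(st.obj, IriRef) and st.obj.iri == _OWL_ONTOLOGY
    ]
    if len(headers) > 1:
        raise LoadError(
            "owl", "multiple owl:Ontology headers in one document",
            path, headers[1].line,
        )
    if not headers:
        return None, None, []
    subj = headers[0].subj
    ontology_iri = subj.iri if isinstance(subj, IriRef) else None
    version_iri = None
    imports: list[str] = []
    for st in statements:
        if st.subj != subj:
            continue
        if st.pred == _OWL_VERSION_IRI and isinstance(st.obj, IriRef):
            version_iri = st.obj.iri
        elif st.pred == _OWL_IMPORTS:
            if not isinstance(st.obj, IriRef):
                raise LoadError(
                    "owl", "owl:imports object is not an IRI", path, st.line
                )
            imports.append(st.obj.iri)
    return ontology_iri, version_iri, imports


def _validate_literals(
    statements: list[RawStatement], path: Optional[str]
) -> None:
    for st in statements:
        obj = st.obj
        if isinstance(obj, LiteralRef) and obj.datatype is not None:
            try:
                parse_literal_value(obj.lexical, obj.datatype)
            except LiteralParseError as exc:
                raise LoadError("rdf", str(exc), path, st.line) from None


def _commit(
    store: TripleStore,
    statements: list[RawStatement],
    path: str,
    ontology_iri: Optional[str],
    version_iri: Optional[str],
    imports: list[str],
) -> DocId:
    ont_node = store.intern_iri(ontology_iri) if ontology_iri else None
    ver_node = store.intern_iri(version_iri) if version_iri else None
    import_nodes = [store.intern_iri(i) for i in imports]
    doc = store.add_doc(path, ont_node, ver_node, import_nodes)

    def term_id(term):
        if isinstance(term, IriRef):
            return store.intern_iri(term.iri)
        if isinstance(term, BlankRef):
            return store.make_blank(doc, term.label)
        dt = store.intern_iri(term.datatype) if term.datatype else None
        return store.intern_literal(term.lexical, dt, term.language)

    for st in statements:
        store.add_triple(term_id(st.subj), store.intern_iri(st.pred),
                         term_id(st.obj), doc)
    logger.info("loaded %s: %d statements", path, len(statements))
    return doc


def load(
    store: TripleStore,
    source: Union[bytes, str, BinaryIO],
    base_iri: str,
    catalog: Optional[Catalog] = None,
    path: Optional[str] = None,
) -> DocId:
    """Load one RDF/XML document from bytes, text, or a binary stream.

    On success the document is registered (ontology/version IRIs taken
    from its ``owl:Ontology`` header) and all statements are interned and
    added under the new DocId, which is returned.  On any error the store
    is unchanged.  With a catalog, the ``owl:imports`` closure is loaded
    too.
    """
    if hasattr(source, "read"):
        source = source.read()
    doc_path = path if path is not None else (base_iri or "<stream>")
    cp = store.checkpoint()
    try:
        doc = _load_single(store, source, base_iri, doc_path)
        if catalog is not None:
            _load_imports(store, doc, catalog)
        return doc
    except LoadError:
        store.rollback(cp)
        raise


def load_file(
    store: TripleStore,
    path: Union[str, os.PathLike],
    catalog: Optional[Catalog] = None,
) -> DocId:
    """Load a document from the filesystem (base IRI = its file IRI).

    With a catalog, every ``owl:imports`` IRI is resolved and loaded
    recursively, each document at most once.  Any failure in the closure
    leaves the store unchanged.
    """
    path = os.fspath(path)
    cp = store.checkpoint()
    try:
        try:
            with open(path, "rb") as fh:
                data = fh.read()
        except OSError as exc:
            raise LoadError("file", str(exc), str(path)) from None
        doc = _load_single(store, data, file_iri(path), os.path.abspath(path))
        if catalog is not None:
            _load_imports(store, doc, catalog)
        return doc
    except LoadError:
        store.rollback(cp)
        raise


def _load_single(
    store: TripleStore,
    data: Union[bytes, str],
    base_iri: str,
    doc_path: str,
) -> DocId:
    if store.doc_by_path(doc_path) is not None:
        raise LoadError("file", "document already loaded", doc_path)
    try:
        statements = parse_rdfxml(data, base_iri)
    except ParseError as exc:
        raise LoadError(exc.stage, exc.message, doc_path, exc.line) from None
    ontology_iri, version_iri, imports = _validate_header(statements, doc_path)
    _validate_literals(statements, doc_path)
    return _commit(store, statements, doc_path, ontology_iri, version_iri,
                   imports)


def _already_loaded(store: TripleStore, iri: str, catalog: Catalog) -> bool:
    for meta in store.docs:
        for nid in (meta.ontology_iri, meta.version_iri):
            if nid is not None and store.iri_str(nid) == iri:
                return True
    try:
        path = catalog.resolve(iri)
    except ResolutionError:
        return False
    return store.doc_by_path(os.path.abspath(path)) is not None


def _load_imports(store: TripleStore, doc: DocId, catalog: Catalog) -> None:
    meta = store[doc]
    for imp in meta.imports:
        iri = store.iri_str(imp)
        if _already_loaded(store, iri, catalog):
            continue
        try:
            target = catalog.resolve(iri)
        except ResolutionError:
            raise LoadError(
                "owl", f"cannot resolve import <{iri}>", meta.path
            ) from None
        if store.doc_by_path(os.path.abspath(target)) is not None:
            continue
        with open(target, "rb") as fh:
            data = fh.read()
        try:
            child = _load_single(
                store, data, file_iri(target), os.path.abspath(target)
            )
        except LoadError:
            raise
        _load_imports(store, child, catalog)
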
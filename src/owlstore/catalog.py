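"""Filesystem catalog of ontology documents for imports resolution.

A :class:`Catalog` maps ontology IRIs, version IRIs, and filesystem paths
to document locations.  :func:`scan_directory` builds one by shallowly
reading the ``owl:Ontology`` header of every candidate file — only as much
of each document as needed — skipping unparseable files with a warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterator, Optional
from urllib.parse import urljoin

from lxml import etree

from . import vocabulary as voc
from .nodes import is_absolute_iri

logger = logging.getLogger(__name__)

_PREFERRED_EXTS = (".owl", ".rdf", ".xml")

_RDF_ABOUT = f"{{{voc.RDF}}}about"
_RDF_RESOURCE = f"{{{voc.RDF}}}resource"
_OWL_ONTOLOGY_TAG = f"{{{voc.OWL}}}Ontology"
_OWL_VERSION_TAG = f"{{{voc.OWL}}}versionIRI"
_OWL_IMPORTS_TAG = f"{{{voc.OWL}}}imports"
_XML_BASE = "{http://www.w3.org/XML/1998/namespace}base"


class ResolutionError(KeyError):
    """No catalog entry matches the requested IRI."""

    def __init__(self, iri: str):
        self.iri = iri
        super().__init__(f"cannot resolve ontology IRI <{iri}>")


@dataclass(frozen=True)
class CatalogEntry:
    """One discovered ontology document."""

    path: str
    ontology_iri: Optional[str]
    version_iri: Optional[str] = None
    imports: tuple[str, ...] = ()


@dataclass(frozen=True)
class OntologyHeader:
    """Shallow-scan result: the identity triple of a document."""

    ontology_iri: Optional[str]
    version_iri: Optional[str]
    imports: tuple[str, ...]


class Catalog:
    """Maps ontology/version IRIs and paths to document files.

    Entry paths are unique; several entries may share an ontology IRI with
    different version IRIs (disambiguated at resolve time).
    """

    def __init__(self) -> None:
        self._entries: dict[str, CatalogEntry] = {}

    def add(self, entry: CatalogEntry) -> None:
        path = os.path.abspath(entry.path)
        self._entries[path] = CatalogEntry(
            path, entry.ontology_iri, entry.version_iri, entry.imports
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(sorted(self._entries.values(), key=lambda e: e.path))

    def resolve(self, iri: str) -> str:
        """Resolve an import IRI to a filesystem path.

        Preference order: exact version-IRI match, then ontology-IRI match
        (several versions: the lexicographically greatest version IRI
        wins), then an exact path match.  No match raises
        :class:`ResolutionError`.
        """
        version_hits = sorted(
            e.path for e in self._entries.values() if e.version_iri == iri
        )
        if version_hits:
            return version_hits[0]
        ontology_hits = [
            e for e in self._entries.values() if e.ontology_iri == iri
        ]
        if ontology_hits:
            best = max(
                ontology_hits,
                key=lambda e: (e.version_iri or "", e.path),
            )
            return best.path
        candidates = {iri}
        if iri.startswith("file://"):
            candidates.add(iri[len("file://"):])
        for cand in candidates:
            if os.path.abspath(cand) in self._entries and os.path.exists(cand):
                return os.path.abspath(cand)
        raise ResolutionError(iri)


def read_header(path: str) -> Optional[OntologyHeader]:
    """Shallowly extract the ``owl:Ontology`` header of an RDF/XML file.

    Streams the XML and stops as soon as the ontology node has been read
    completely; returns ``None`` when the document has no header.  Raises
    ``lxml`` parse errors on malformed XML (callers decide whether to
    skip).
    """
    base = "file://" + os.path.abspath(path)
    with open(path, "rb") as fh:
        context = etree.iterparse(fh, events=("start", "end"), huge_tree=True)
        depth = 0
        for event, el in context:
            if event == "start":
                xml_base = el.get(_XML_BASE)
                if xml_base is not None:
                    base = (
                        xml_base if is_absolute_iri(xml_base)
                        else urljoin(base, xml_base)
                    )
                depth += 1
                if depth > 2 and el.tag != _OWL_ONTOLOGY_TAG:
                    # header, if any, is a top-level (or root) node element
                    pass
                continue
            depth -= 1
            if el.tag != _OWL_ONTOLOGY_TAG:
                if depth <= 1:
                    el.clear()  # free completed top-level nodes only
                continue
            about = el.get(_RDF_ABOUT)
            ontology_iri = (
                (about if is_absolute_iri(about) else urljoin(base, about))
                if about is not None and about != "" else (base if about == "" else None)
            )
            version_iri = None
            imports = []
            for child in el:
                if not isinstance(child.tag, str):
                    continue
                res = child.get(_RDF_RESOURCE)
                if res is None:
                    continue
                res_iri = res if is_absolute_iri(res) else urljoin(base, res)
                if child.tag == _OWL_VERSION_TAG:
                    version_iri = res_iri
                elif child.tag == _OWL_IMPORTS_TAG:
                    imports.append(res_iri)
            return OntologyHeader(ontology_iri, version_iri, tuple(imports))
    return None


def scan_directory(root: str, recurse: bool = True) -> Catalog:
    """Scan a directory for ontology documents and build a catalog.

    Files whose content yields an ``owl:Ontology`` header are entered;
    unparseable or header-less files are skipped with a logged warning.
    Files with the usual ontology extensions are tried first.
    """
    if not os.path.isdir(root):
        raise FileNotFoundError(f"no such directory: {root!r}")
    catalog = Catalog()
    paths: list[str] = []
    if recurse:
        for dirpath, _dirnames, filenames in os.walk(root):
            paths.extend(os.path.join(dirpath, f) for f in filenames)
    else:
        paths = [
            os.path.join(root, f)
            for f in os.listdir(root)
            if os.path.isfile(os.path.join(root, f))
        ]
    paths.sort(
        key=lambda p: (os.path.splitext(p)[1] not in _PREFERRED_EXTS, p)
    )
    for path in paths:
        try:
            header = read_header(path)
        except (etree.XMLSyntaxError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        if header is None:
            logger.warning("skipping %s: no owl:Ontology header", path)
            continue
        catalog.add(
            CatalogEntry(
                path, header.ontology_iri, header.version_iri, header.imports
            )
        )
    return catalog
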
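"""Strict RDF/XML parser producing raw statements.

The parser turns an RDF/XML document into a sequence of
:class:`RawStatement` triples of string-level terms (IRIs, blank-node
labels, literals), in document order, without touching any store.  It
covers the constructs used by OWL ontology documents: ``rdf:RDF`` roots or
bare node elements, ``rdf:Description`` and typed node elements,
``rdf:about`` / ``rdf:ID`` / ``rdf:nodeID``, property elements with
``rdf:resource`` / ``rdf:nodeID`` / ``rdf:datatype`` / ``xml:lang``,
property attributes, nested node elements, ``rdf:parseType`` ``Resource``,
``Collection``, and ``Literal``, plus scoped ``xml:base`` / ``xml:lang``
and relative-IRI resolution.

Violations abort parsing with a :class:`ParseError` carrying the stage
(``xml`` for malformed XML, ``rdf`` for RDF/XML violations) and the source
line.  Containers (``rdf:li``), reification via ``rdf:ID`` on property
elements, and unknown ``rdf:parseType`` values are rejected rather than
guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union
from urllib.parse import urljoin

from lxml import etree

from . import vocabulary as voc
from .nodes import is_absolute_iri

XML_NS = "http://www.w3.org/XML/1998/namespace"
_XML_BASE = f"{{{XML_NS}}}base"
_XML_LANG = f"{{{XML_NS}}}lang"

_RDF = voc.RDF
_RDF_RDF = f"{{{_RDF}}}RDF"
_RDF_DESCRIPTION = f"{{{_RDF}}}Description"
_A_ABOUT = f"{{{_RDF}}}about"
_A_ID = f"{{{_RDF}}}ID"
_A_NODEID = f"{{{_RDF}}}nodeID"
_A_RESOURCE = f"{{{_RDF}}}resource"
_A_DATATYPE = f"{{{_RDF}}}datatype"
_A_PARSETYPE = f"{{{_RDF}}}parseType"

# rdf: names that are pure syntax markers, not terms
_SYNTAX_ATTRS = {_A_ABOUT, _A_ID, _A_NODEID, _A_RESOURCE, _A_DATATYPE,
                 _A_PARSETYPE}
_FORBIDDEN_NODE_NAMES = {
    "RDF", "ID", "about", "parseType", "resource", "nodeID", "datatype",
    "li", "aboutEach", "aboutEachPrefix", "bagID",
}


@dataclass(frozen=True)
class IriRef:
    """An IRI term at the parse level."""

    iri: str


@dataclass(frozen=True)
class BlankRef:
    """A blank-node term, identified by a document-local label."""

    label: str


@dataclass(frozen=True)
class LiteralRef:
    """A literal term: lexical form, optional datatype IRI, language tag."""

    lexical: str
    datatype: Optional[str] = None
    language: str = ""


Term = Union[IriRef, BlankRef, LiteralRef]


@dataclass(frozen=True)
class RawStatement:
    """One RDF statement in string-level form, with its source line."""

    subj: Union[IriRef, BlankRef]
    pred: str
    obj: Term
    line: Optional[int] = None


class ParseError(Exception):
    """XML- or RDF-level parse failure."""

    def __init__(self, stage: str, message: str, line: Optional[int] = None):
        self.stage = stage
        self.line = line
        at = f" (line {line})" if line is not None else ""
        super().__init__(f"{stage}: {message}{at}")
        self.message = message


def _tag_iri(el) -> str:
    tag = el.tag
    if not isinstance(tag, str) or not tag.startswith("{"):
        raise ParseError(
            "rdf", f"element {tag!r} has no namespace", el.sourceline
        )
    ns, name = tag[1:].split("}", 1)
    return ns + name


class _Parser:
    def __init__(self, base_iri: str):
        self.base_iri = base_iri or ""
        self.statements: list[RawStatement] = []
        self._anon = 0
        self._seen_ids: set[str] = set()

    # -- helpers ------------------------------------------------------------

    def _fresh_blank(self) -> BlankRef:
        self._anon += 1
        # '#' cannot occur in an NCName, so generated labels never collide
        # with user-supplied rdf:nodeID labels
        return BlankRef(f"#anon{self._anon}")

    def _resolve(self, ref: str, base: str, line) -> str:
        if is_absolute_iri(ref):
            return ref
        if not base:
            raise ParseError(
                "rdf", f"relative IRI {ref!r} with no base IRI", line
            )
        return urljoin(base, ref)

    def _emit(self, subj, pred: str, obj, line) -> None:
        self.statements.append(RawStatement(subj, pred, obj, line))

    # -- node elements -------------------------------------------------------

    def node_element(self, el, base: str, lang: str) -> Union[IriRef, BlankRef]:
        base = self._scoped_base(el, base)
        lang = el.get(_XML_LANG, lang)
        line = el.sourceline
        tag = _tag_iri(el)
        if tag.startswith(_RDF) and tag[len(_RDF):] in _FORBIDDEN_NODE_NAMES:
            raise ParseError("rdf", f"illegal node element {tag!r}", line)

        about = el.get(_A_ABOUT)
        rdf_id = el.get(_A_ID)
        node_id = el.get(_A_NODEID)
        if sum(x is not None for x in (about, rdf_id, node_id)) > 1:
            raise ParseError(
                "rdf", "node element with more than one of rdf:about, "
                "rdf:ID, rdf:nodeID", line,
            )
        subj: Union[IriRef, BlankRef]
        if about is not None:
            subj = IriRef(self._resolve(about, base, line))
        elif rdf_id is not None:
            iri = self._resolve("#" + rdf_id, base, line)
            if iri in self._seen_ids:
                raise ParseError("rdf", f"rdf:ID {rdf_id!r} reused", line)
            self._seen_ids.add(iri)
            subj = IriRef(iri)
        elif node_id is not None:
            subj = BlankRef(node_id)
        else:
            subj = self._fresh_blank()

        if tag != _RDF + "Description":
            self._emit(subj, _RDF + "type", IriRef(tag), line)

        for attr, value in el.attrib.items():
            if attr in _SYNTAX_ATTRS or attr in (_XML_BASE, _XML_LANG):
                continue
            if not attr.startswith("{"):
                raise ParseError(
                    "rdf", f"unqualified attribute {attr!r}", line
                )
            attr_iri = attr[1:].replace("}", "", 1)
            if attr_iri.startswith(XML_NS):
                continue
            if attr_iri == _RDF + "type":
                self._emit(subj, attr_iri,
                           IriRef(self._resolve(value, base, line)), line)
            elif attr_iri.startswith(_RDF) and attr_iri[len(_RDF):] in _FORBIDDEN_NODE_NAMES:
                raise ParseError(
                    "rdf", f"illegal property attribute {attr_iri!r}", line
                )
            else:
                self._emit(subj, attr_iri, LiteralRef(value, None, lang), line)

        for child in el:
            if isinstance(child.tag, str):
                self.property_element(subj, child, base, lang)
        return subj

    def _scoped_base(self, el, base: str) -> str:
        new_base = el.get(_XML_BASE)
        if new_base is None:
            return base
        if is_absolute_iri(new_base):
            return new_base
        if not base:
            raise ParseError(
                "rdf", f"relative xml:base {new_base!r} with no outer base",
                el.sourceline,
            )
        return urljoin(base, new_base)

    # -- property elements -----------------------------------------------------

    def property_element(self, subj, el, base: str, lang: str) -> None:
        base = self._scoped_base(el, base)
        lang = el.get(_XML_LANG, lang)
        line = el.sourceline
        pred = _tag_iri(el)
        if pred == _RDF + "li":
            raise ParseError("rdf", "rdf:li containers are not supported", line)
        if pred.startswith(_RDF) and pred[len(_RDF):] in (
            "Description", "RDF", "about", "ID", "nodeID", "resource",
            "datatype", "parseType", "aboutEach", "aboutEachPrefix", "bagID",
        ):
            raise ParseError("rdf", f"illegal property element {pred!r}", line)
        if el.get(_A_ID) is not None:
            raise ParseError(
                "rdf", "rdf:ID on a property element (reification) is not "
                "supported", line,
            )

        parse_type = el.get(_A_PARSETYPE)
        resource = el.get(_A_RESOURCE)
        node_id = el.get(_A_NODEID)
        datatype = el.get(_A_DATATYPE)
        children = [c for c in el if isinstance(c.tag, str)]
        text = (el.text or "") + "".join(
            (c.tail or "") for c in el
        )

        prop_attrs = {}
        for attr, value in el.attrib.items():
            if attr in _SYNTAX_ATTRS or attr in (_XML_BASE, _XML_LANG):
                continue
            if not attr.startswith("{"):
                raise ParseError("rdf", f"unqualified attribute {attr!r}", line)
            attr_iri = attr[1:].replace("}", "", 1)
            if attr_iri.startswith(XML_NS):
                continue
            prop_attrs[attr_iri] = value

        if parse_type is not None:
            if resource or node_id or datatype or prop_attrs:
                raise ParseError(
                    "rdf", "rdf:parseType combined with other attributes", line
                )
            if parse_type == "Resource":
                inner = self._fresh_blank()
                self._emit(subj, pred, inner, line)
                for child in children:
                    self.property_element(inner, child, base, lang)
            elif parse_type == "Collection":
                members = [
                    self.node_element(child, base, lang) for child in children
                ]
                if not members:
                    self._emit(subj, pred, IriRef(_RDF + "nil"), line)
                    return
                links = [self._fresh_blank() for _ in members]
                self._emit(subj, pred, links[0], line)
                for i, member in enumerate(members):
                    self._emit(links[i], _RDF + "first", member, line)
                    nxt = links[i + 1] if i + 1 < len(members) else IriRef(_RDF + "nil")
                    self._emit(links[i], _RDF + "rest", nxt, line)
            elif parse_type == "Literal":
                raw = (el.text or "") + "".join(
                    etree.tostring(c, encoding="unicode") for c in el
                )
                self._emit(
                    subj, pred,
                    LiteralRef(raw, _RDF + "XMLLiteral", ""), line,
                )
            else:
                raise ParseError(
                    "rdf", f"unknown rdf:parseType {parse_type!r}", line
                )
            return

        if resource is not None or node_id is not None:
            if resource is not None and node_id is not None:
                raise ParseError(
                    "rdf", "both rdf:resource and rdf:nodeID on a property "
                    "element", line,
                )
            if children or text.strip():
                raise ParseError(
                    "rdf", "property element with rdf:resource/rdf:nodeID "
                    "must be empty", line,
                )
            if resource is not None:
                obj: Term = IriRef(self._resolve(resource, base, line))
            else:
                obj = BlankRef(node_id)
            if prop_attrs:
                raise ParseError(
                    "rdf", "property attributes combined with "
                    "rdf:resource/rdf:nodeID", line,
                )
            self._emit(subj, pred, obj, line)
            return

        if children:
            if text.strip():
                raise ParseError(
                    "rdf", "property element mixes text and element content",
                    line,
                )
            if len(children) != 1:
                raise ParseError(
                    "rdf", "property element with more than one node element",
                    line,
                )
            if datatype is not None or prop_attrs:
                raise ParseError(
                    "rdf", "attributes combined with element content", line
                )
            inner = self.node_element(children[0], base, lang)
            self._emit(subj, pred, inner, line)
            return

        if datatype is not None:
            dt = self._resolve(datatype, base, line)
            self._emit(subj, pred, LiteralRef(el.text or "", dt, ""), line)
            return

        if prop_attrs:
            if text.strip():
                raise ParseError(
                    "rdf", "property attributes combined with text content",
                    line,
                )
            inner = self._fresh_blank()
            self._emit(subj, pred, inner, line)
            for attr_iri, value in prop_attrs.items():
                if attr_iri == _RDF + "type":
                    self._emit(inner, attr_iri,
                               IriRef(self._resolve(value, base, line)), line)
                else:
                    self._emit(inner, attr_iri,
                               LiteralRef(value, None, lang), line)
            return

        self._emit(subj, pred, LiteralRef(el.text or "", None, lang), line)


def parse_rdfxml(
    data: Union[bytes, str], base_iri: str = ""
) -> list[RawStatement]:
    """Parse RDF/XML bytes (or text) into raw statements in document order.

    Raises :class:`ParseError` with stage ``"xml"`` for malformed XML and
    ``"rdf"`` for RDF/XML violations; both carry the source line.
    """
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data, parser=etree.XMLParser(huge_tree=True))
    except etree.XMLSyntaxError as exc:
        line = exc.lineno if exc.lineno else None
        raise ParseError("xml", str(exc.msg or exc), line) from None
    parser = _Parser(base_iri)
    base = parser._scoped_base(root, parser.base_iri)
    lang = root.get(_XML_LANG, "")
    if root.tag == _RDF_RDF:
        for child in root:
            if isinstance(child.tag, str):
                parser.node_element(child, base, lang)
    else:
        parser.node_element(root, base, lang)
    return parser.statements


def statement_counts(statements: Iterable[RawStatement]) -> dict[str, int]:
    """Tally of statements by object kind (iri / blank / literal)."""
    out = {"iri": 0, "blank": 0, "literal": 0}
    for st in statements:
        if isinstance(st.obj, IriRef):
            out["iri"] += 1
        elif isinstance(st.obj, BlankRef):
            out["blank"] += 1
        else:
            out["literal"] += 1
    return out
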
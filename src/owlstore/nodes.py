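"""RDF term hierarchy: IRI, literal, and blank nodes.

Literal payloads are stored as native Python values parsed according to
their XSD datatype (bool, int, Decimal, float, or str), so node identity is
defined by *value* equality under the datatype rather than by lexical
equality: ``"1"^^xsd:boolean`` and ``"true"^^xsd:boolean`` intern to the
same node.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Union

from . import vocabulary as voc
from .ids import DocId, NodeId, NsId


class LiteralParseError(ValueError):
    """Lexical form is invalid for the stated datatype."""

    def __init__(self, lexical: str, datatype_iri: str):
        self.lexical = lexical
        self.datatype_iri = datatype_iri
        super().__init__(
            f"invalid lexical form {lexical!r} for datatype <{datatype_iri}>"
        )


@dataclass(frozen=True)
class NodeIri:
    """An IRI term: interned namespace prefix plus optional fragment."""

    id: NodeId
    ns: NsId
    fragment: str


@dataclass(frozen=True)
class NodeLiteral:
    """A typed literal with a parsed payload and optional language tag."""

    id: NodeId
    datatype: NodeId
    value: Union[bool, int, float, Decimal, str]
    language: str = ""
    lexical: str = ""  # original lexical form, kept for round-tripping


@dataclass(frozen=True)
class NodeBlank:
    """A blank node, scoped to the document that introduced it."""

    id: NodeId
    doc: DocId
    ordinal: int


Node = Union[NodeIri, NodeLiteral, NodeBlank]


@dataclass(frozen=True)
class DocMeta:
    """Descriptor of a loaded ontology document."""

    id: DocId
    path: str
    ontology_iri: NodeId | None = None
    version_iri: NodeId | None = None
    imports: tuple[NodeId, ...] = field(default=(), compare=False)


# --- literal parsing / canonicalization ------------------------------------

_INT_RANGES = {
    "integer": None,
    "long": (-(2**63), 2**63 - 1),
    "int": (-(2**31), 2**31 - 1),
    "short": (-(2**15), 2**15 - 1),
    "byte": (-(2**7), 2**7 - 1),
    "nonNegativeInteger": (0, None),
    "positiveInteger": (1, None),
    "nonPositiveInteger": (None, 0),
    "negativeInteger": (None, -1),
    "unsignedLong": (0, 2**64 - 1),
    "unsignedInt": (0, 2**32 - 1),
    "unsignedShort": (0, 2**16 - 1),
    "unsignedByte": (0, 2**8 - 1),
}

_INT_RE = re.compile(r"^[+-]?[0-9]+$")
_FLOAT_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def split_iri(iri: str) -> tuple[str, str]:
    """Split an absolute IRI into (namespace prefix, fragment).

    The split point is after the last ``#`` if present, else after the last
    ``/``; concatenating the parts reconstructs the input exactly.
    """
    if not iri:
        raise ValueError("empty IRI")
    hash_pos = iri.rfind("#")
    if hash_pos >= 0:
        return iri[: hash_pos + 1], iri[hash_pos + 1:]
    slash_pos = iri.rfind("/")
    if slash_pos >= 0:
        return iri[: slash_pos + 1], iri[slash_pos + 1:]
    # scheme-only IRIs like "urn:x" split after the colon
    colon_pos = iri.rfind(":")
    if colon_pos >= 0:
        return iri[: colon_pos + 1], iri[colon_pos + 1:]
    raise ValueError(f"not an absolute IRI: {iri!r}")


def is_absolute_iri(iri: str) -> bool:
    return bool(re.match(r"^[A-Za-z][A-Za-z0-9+.-]*:", iri))


def parse_literal_value(lexical: str, datatype_iri: str):
    """Parse a lexical form under an XSD datatype.

    Returns ``(value, canonical_key)`` where *canonical_key* is hashable and
    equal for value-equal literals.  Unknown datatypes keep the raw lexical
    form as both value and key.  Raises :class:`LiteralParseError` on
    invalid forms for the recognized numeric/boolean datatypes.
    """
    if not datatype_iri.startswith(voc.XSD):
        return lexical, lexical
    name = datatype_iri[len(voc.XSD):]
    if name == "boolean":
        s = lexical.strip()
        if s in ("true", "1"):
            return True, True
        if s in ("false", "0"):
            return False, False
        raise LiteralParseError(lexical, datatype_iri)
    if name in _INT_RANGES:
        s = lexical.strip()
        if not _INT_RE.match(s):
            raise LiteralParseError(lexical, datatype_iri)
        value = int(s)
        rng = _INT_RANGES[name]
        if rng is not None:
            lo, hi = rng
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                raise LiteralParseError(lexical, datatype_iri)
        return value, value
    if name == "decimal":
        try:
            value = Decimal(lexical.strip())
        except InvalidOperation:
            raise LiteralParseError(lexical, datatype_iri) from None
        if not value.is_finite():
            raise LiteralParseError(lexical, datatype_iri)
        return value, str(value.normalize())
    if name in ("float", "double"):
        s = lexical.strip()
        if s in ("INF", "+INF"):
            return math.inf, "INF"
        if s == "-INF":
            return -math.inf, "-INF"
        if s == "NaN":
            return math.nan, "NaN"
        if not _FLOAT_RE.match(s):
            raise LiteralParseError(lexical, datatype_iri)
        value = float(s)
        return value, repr(value)
    return lexical, lexical
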
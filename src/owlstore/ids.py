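"""Light-weight opaque identifiers for store objects.

Namespaces, nodes, and documents are referred to by small integer IDs,
interned once per store.  The three ID kinds are distinct types so that a
lookup with the wrong kind fails loudly instead of silently returning the
wrong object.
"""

from __future__ import annotations


class NsId(int):
    """Identifier of a namespace (prefix) IRI."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NsId({int(self)})"


class NodeId(int):
    """Identifier of an RDF term (IRI, literal, or blank node)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NodeId({int(self)})"


class DocId(int):
    """Identifier of a loaded ontology document."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DocId({int(self)})"
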
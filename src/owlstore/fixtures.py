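"""Synthetic ontology documents, query workloads, and the index study.

Every other module is testable without downloads: :func:`generate_document`
emits a deterministic RDF/XML ontology from an :class:`OntologySpec`
together with its expected statement multiset and expected axiom multiset
(computed in closed form), or — for error-injected variants — the stage at
which loading must fail.  :func:`generate_workload` draws triple-pattern
query workloads, including the classic benchmark pattern of a random
subject combined with the constant ``rdfs:subClassOf`` predicate.
:func:`index_study` compares index configurations by the number of element
comparisons needed to answer a workload, asserting identical results.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import vocabulary as voc
from .store import (
    ComparisonCounter,
    TriplePattern,
    TripleStore,
)

_ERROR_STAGES = {
    "xml_truncated": "xml",
    "rdf_duplicate_id": "rdf",
    "owl_two_ontologies": "owl",
    "owl_undeclared_predicate": "owl",
    "owl_misspelled_term": "owl",
}

#: injections that load fine but fail strict axiom mapping
MAPPING_STAGE_INJECTIONS = frozenset(
    {"owl_undeclared_predicate", "owl_misspelled_term"}
)

#: error_injection values and the loading/mapping stage they break.
ERROR_INJECTIONS = tuple(_ERROR_STAGES)


@dataclass(frozen=True)
class OntologySpec:
    """Parameters of one synthetic ontology document.

    The expected statement and axiom counts are closed-form functions of
    the fields; ``expected_statement_count`` / ``expected_axiom_count``
    compute them.
    """

    n_classes: int = 10
    n_object_properties: int = 2
    n_subclass_links: int = 5
    n_restrictions: int = 2
    n_annotations: int = 3
    n_imports: int = 0
    error_injection: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subclass_links > self.n_classes * self.n_classes:
            raise ValueError("more subclass links than class pairs")
        if self.n_restrictions and (
            not self.n_classes or not self.n_object_properties
        ):
            raise ValueError("restrictions need classes and a property")
        if self.error_injection is not None \
                and self.error_injection not in _ERROR_STAGES:
            raise ValueError(
                f"unknown error injection {self.error_injection!r}"
            )

    @property
    def ontology_iri(self) -> str:
        return f"http://example.org/onto/{self.seed}"

    @property
    def entity_ns(self) -> str:
        return f"http://example.org/onto/{self.seed}#"

    @property
    def error_stage(self) -> Optional[str]:
        return _ERROR_STAGES.get(self.error_injection or "", None)

    def expected_statement_count(self) -> int:
        return (
            1 + self.n_imports
            + self.n_classes + self.n_object_properties
            + self.n_subclass_links
            + 4 * self.n_restrictions
            + self.n_annotations
        )

    def expected_axiom_count(self) -> int:
        # header + declarations + subclass axioms (plain and via
        # restriction) + annotation assertions
        return (
            1
            + self.n_classes + self.n_object_properties
            + self.n_subclass_links + self.n_restrictions
            + self.n_annotations
        )


@dataclass(frozen=True)
class GeneratedDocument:
    """A generated RDF/XML document plus its closed-form expectations.

    ``statements`` are string-level ``(subject, predicate, object)``
    triples where resources are IRI strings, blank nodes are ``_:label``,
    and literals are ``("lit", lexical, datatype_iri_or_None, lang)``
    tuples.  ``axioms`` are expected functional-syntax-level tuples (see
    tests) or ``None`` for error-injected documents, in which case
    ``expected_error_stage`` names the stage that must fail.
    """

    spec: OntologySpec
    text: str
    statements: tuple
    axioms: Optional[tuple]
    expected_error_stage: Optional[str] = None


def _pairs(rng: random.Random, n_classes: int, count: int) -> list:
    pairs = []
    seen = set()
    while len(pairs) < count:
        i = rng.randrange(n_classes)
        j = rng.randrange(n_classes)
        if (i, j) in seen:
            continue
        seen.add((i, j))
        pairs.append((i, j))
    return pairs


def generate_document(spec: OntologySpec) -> GeneratedDocument:
    """Emit a deterministic RDF/XML ontology document for *spec*.

    Valid specs come with the expected statement and axiom multisets;
    error-injected specs instead state the loading/mapping stage that must
    fail (``xml``, ``rdf``, or ``owl``).
    """
    rng = random.Random(spec.seed)
    ns = spec.entity_ns
    ont = spec.ontology_iri
    rdf_type = voc.RDF + "type"

    lines = [
        '<?xml version="1.0"?>',
        '<rdf:RDF xmlns:rdf="%s"' % voc.RDF,
        '         xmlns:rdfs="%s"' % voc.RDFS,
        '         xmlns:owl="%s"' % voc.OWL,
        '         xmlns:ex="%s">' % ns,
    ]
    statements: list = []

    imports = [f"http://example.org/imported/{spec.seed}/{k}"
               for k in range(spec.n_imports)]
    lines.append(f'  <owl:Ontology rdf:about="{ont}">')
    statements.append((ont, rdf_type, voc.OWL + "Ontology"))
    for imp in imports:
        lines.append(f'    <owl:imports rdf:resource="{imp}"/>')
        statements.append((ont, voc.OWL + "imports", imp))
    lines.append('  </owl:Ontology>')

    classes = [f"{ns}C{i}" for i in range(spec.n_classes)]
    props = [f"{ns}p{i}" for i in range(spec.n_object_properties)]
    for c in classes:
        lines.append(f'  <owl:Class rdf:about="{c}"/>')
        statements.append((c, rdf_type, voc.OWL + "Class"))
    for p in props:
        lines.append(f'  <owl:ObjectProperty rdf:about="{p}"/>')
        statements.append((p, rdf_type, voc.OWL + "ObjectProperty"))

    links = _pairs(rng, spec.n_classes, spec.n_subclass_links) \
        if spec.n_classes else []
    for i, j in links:
        lines.append(
            f'  <rdf:Description rdf:about="{classes[i]}">\n'
            f'    <rdfs:subClassOf rdf:resource="{classes[j]}"/>\n'
            f'  </rdf:Description>'
        )
        statements.append(
            (classes[i], voc.RDFS + "subClassOf", classes[j])
        )

    restrictions = []
    for k in range(spec.n_restrictions):
        ci = rng.randrange(spec.n_classes)
        pj = rng.randrange(spec.n_object_properties)
        ck = rng.randrange(spec.n_classes)
        restrictions.append((ci, pj, ck))
        label = f"r{k}"
        lines.append(
            f'  <rdf:Description rdf:about="{classes[ci]}">\n'
            f'    <rdfs:subClassOf rdf:nodeID="{label}"/>\n'
            f'  </rdf:Description>\n'
            f'  <rdf:Description rdf:nodeID="{label}">\n'
            f'    <rdf:type rdf:resource="{voc.OWL}Restriction"/>\n'
            f'    <owl:onProperty rdf:resource="{props[pj]}"/>\n'
            f'    <owl:someValuesFrom rdf:resource="{classes[ck]}"/>\n'
            f'  </rdf:Description>'
        )
        blank = "_:" + label
        statements.extend([
            (classes[ci], voc.RDFS + "subClassOf", blank),
            (blank, rdf_type, voc.OWL + "Restriction"),
            (blank, voc.OWL + "onProperty", props[pj]),
            (blank, voc.OWL + "someValuesFrom", classes[ck]),
        ])

    annotations = []
    for k in range(spec.n_annotations):
        ci = rng.randrange(spec.n_classes)
        text = f"class number {ci} (note {k})"
        annotations.append((ci, text))
        lines.append(
            f'  <rdf:Description rdf:about="{classes[ci]}">\n'
            f'    <rdfs:label>{text}</rdfs:label>\n'
            f'  </rdf:Description>'
        )
        statements.append(
            (classes[ci], voc.RDFS + "label", ("lit", text, None, ""))
        )

    expected_error = spec.error_stage
    if spec.error_injection == "owl_undeclared_predicate":
        lines.append(
            f'  <rdf:Description rdf:about="{classes[0]}">\n'
            f'    <ex:partOf rdf:resource="{classes[-1]}"/>\n'
            f'  </rdf:Description>'
        )
        statements.append((classes[0], ns + "partOf", classes[-1]))
    elif spec.error_injection == "owl_misspelled_term":
        lines.append(f'  <owl:Classs rdf:about="{ns}Broken"/>')
        statements.append((ns + "Broken", rdf_type, voc.OWL + "Classs"))
    elif spec.error_injection == "owl_two_ontologies":
        lines.append(
            f'  <owl:Ontology rdf:about="{ont}-again"/>'
        )
    elif spec.error_injection == "rdf_duplicate_id":
        lines.append(f'  <owl:Class rdf:ID="dup"/>')
        lines.append(f'  <owl:Class rdf:ID="dup"/>')
    lines.append('</rdf:RDF>')
    text = "\n".join(lines) + "\n"

    if spec.error_injection == "xml_truncated":
        text = text[: int(len(text) * 0.8)]

    if expected_error is not None:
        return GeneratedDocument(
            spec, text, tuple(statements), None, expected_error
        )

    axioms: list = [("Ontology", ont, tuple(imports))]
    axioms += [("Declaration", "Class", c) for c in classes]
    axioms += [("Declaration", "ObjectProperty", p) for p in props]
    axioms += [
        ("SubClassOf", ("C", classes[i]), ("C", classes[j]))
        for i, j in links
    ]
    axioms += [
        ("SubClassOf", ("C", classes[ci]),
         ("some", props[pj], ("C", classes[ck])))
        for ci, pj, ck in restrictions
    ]
    axioms += [
        ("AnnotationAssertion", voc.RDFS + "label", classes[ci],
         ("lit", text, None, ""))
        for ci, text in annotations
    ]
    return GeneratedDocument(spec, text, tuple(statements), tuple(axioms))


# --------------------------------------------------------------------------
# random stores and workloads
# --------------------------------------------------------------------------


def random_store(
    n_triples: int,
    seed: int,
    n_subjects: int = 0,
    n_predicates: int = 0,
    n_objects: int = 0,
    n_docs: int = 2,
    index_config=None,
) -> TripleStore:
    """A store filled with random triples over a bounded ID universe.

    Defaults scale the term universe with the triple count so that typical
    patterns match more than one triple.  A share of the predicates is the
    constant ``rdfs:subClassOf``, mirroring ontology-like workloads.
    """
    rng = random.Random(seed)
    n_subjects = n_subjects or max(4, n_triples // 10)
    n_predicates = n_predicates or max(2, n_triples // 200)
    n_objects = n_objects or max(4, n_triples // 10)
    store = TripleStore(index_config)
    docs = [store.add_doc(f"mem://doc{i}") for i in range(n_docs)]
    base = f"http://example.org/rand/{seed}#"
    subjects = [store.intern_iri(f"{base}s{i}") for i in range(n_subjects)]
    predicates = [voc.RDFS_SUBCLASSOF] + [
        store.intern_iri(f"{base}p{i}") for i in range(n_predicates - 1)
    ]
    objects = [store.intern_iri(f"{base}o{i}") for i in range(n_objects)]
    while store.n_triples < n_triples:
        store.add_triple(
            rng.choice(subjects),
            rng.choice(predicates),
            rng.choice(objects),
            rng.choice(docs),
        )
    return store


def generate_workload(
    store: TripleStore,
    n_queries: int,
    seed: int,
    mode: str = "paper",
) -> list[TriplePattern]:
    """Draw a reproducible triple-pattern workload against *store*.

    ``mode="paper"`` mirrors the classic store benchmark: each query binds
    a random subject and the constant predicate ``rdfs:subClassOf``.
    ``mode="all_combos"`` cycles uniformly through all 16 combinations of
    constrained positions, binding values drawn from the store's triples
    (occasionally foreign IDs, to exercise empty results).
    """
    rng = random.Random(seed)
    triples = store.triples
    if not triples:
        return []
    if mode == "paper":
        subjects = sorted({t.subj for t in triples})
        return [
            TriplePattern(
                subj=rng.choice(subjects), pred=voc.RDFS_SUBCLASSOF
            )
            for _ in range(n_queries)
        ]
    if mode != "all_combos":
        raise ValueError(f"unknown workload mode {mode!r}")
    patterns = []
    for q in range(n_queries):
        mask = q % 16
        t = rng.choice(triples)
        patterns.append(
            TriplePattern(
                subj=t.subj if mask & 1 else None,
                pred=t.pred if mask & 2 else None,
                obj=t.obj if mask & 4 else None,
                doc=t.doc if mask & 8 else None,
            )
        )
    return patterns


def index_study(
    store: TripleStore,
    configs: Sequence[Sequence[str]],
    workload: Sequence[TriplePattern],
) -> list[tuple[str, int]]:
    """Compare index configurations by element-comparison counts.

    Re-indexes the store's contents under each configuration, answers the
    whole workload, and returns ``(config, comparisons)`` rows.  Result
    multisets are asserted identical across configurations.
    """
    if not configs:
        raise ValueError("at least one index configuration is required")
    rows: list[tuple[str, int]] = []
    reference: Optional[list] = None
    for config in configs:
        variant = store.reindexed(config)
        counter = ComparisonCounter()
        results = []
        for pattern in workload:
            results.append(
                sorted(variant.find_triples(pattern, counter=counter))
            )
        if reference is None:
            reference = results
        elif results != reference:
            raise AssertionError(
                f"index configuration {','.join(map(str, config))} changed "
                "query results"
            )
        rows.append((",".join(str(c) for c in config), counter.comparisons))
    return rows


#: The index-study design space: all four bin choices, two sort orders each.
STUDY_CONFIGS: tuple[tuple[str, ...], ...] = (
    ("s:pod",),
    ("s:dop",),
    ("p:sod",),
    ("p:dos",),
    ("o:psd",),
    ("o:dsp",),
    ("d:spo",),
    ("d:ops",),
    ("s:pod", "o:psd"),  # the default two-index configuration
)
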
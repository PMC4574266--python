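# owlstore

An index-backed, in-memory RDF triple store with a strict transactional
RDF/XML loader and a strict translator from RDF graphs to OWL 2 axioms —
the processing stack that sits underneath working with biomedical
ontologies (OBO-family and similar) before any reasoning happens.

## Who this is for

Ontology tooling needs three things done fast and done strictly: load
RDF/XML ontology documents (including their `owl:imports` closure resolved
against local files), hold millions of triples compactly and answer
triple-pattern queries, and turn the triples into OWL 2 structural axioms
without silently misreading them.  `owlstore` provides these as a Python
library plus a small CLI.  Reasoning, serialization back to RDF/XML, and
non-RDF/XML syntaxes are out of scope.

## Design

**Interned terms behind integer IDs.** Namespace prefix IRIs (`NsId`), RDF
terms (`NodeId`), and document descriptors (`DocId`) are interned once per
store.  An IRI node is a namespace prefix plus fragment (split at the last
`#`, else the last `/`); a literal node stores its payload parsed under
its XSD datatype, so `"1"^^xsd:boolean` and `"true"^^xsd:boolean` are the
same node; a blank node is scoped to its source document, so equal labels
from different documents never collide.  The standard RDF/RDFS/OWL 2/XSD
vocabulary is pre-interned with fixed IDs, identical across stores and
runs.

**Binned, sorted triple indices.** A triple is `(subject, predicate,
object, document)` — generalized, with no positional type restrictions.
Each configured index bins triples by one term and keeps each bin sorted
by the remaining three; the default configuration is `s:pod` (bin by
subject, sort by predicate, object, document) plus `o:psd`.  For a query
pattern, `find_triples` automatically selects the index whose bin key is
constrained and whose sort order covers the most additionally constrained
terms as a prefix, resolved by binary search; otherwise it falls back to a
full scan.  Results are a lazy iterator: test emptiness, take the first
match, or consume all matches.

**Transactional, strict loading.** A document is parsed and validated
completely — XML well-formedness, RDF/XML structure, literal lexical
forms, the OWL header — before the store is touched; any failure (at the
`file`, `xml`, `rdf`, or `owl` stage) raises a `LoadError` carrying the
location and leaves the store exactly as it was, imports closure included.
A `Catalog` built by scanning a directory (shallowly reading each file's
`owl:Ontology` header) resolves import IRIs to paths: version-IRI match
first, then ontology IRI, then path.  Documents are never fetched from the
Internet.

**Strict axiom mapping.** `map_axioms` follows the standard reverse
mapping from RDF graphs to OWL 2 axioms in two passes (declarations, then
axiom triples), resolving class expressions anchored at blank nodes —
intersections, unions, complements, enumerations, and property
restrictions such as `ObjectSomeValuesFrom(p C)` or qualified
cardinalities.  Every triple must be consumed exactly once; an undeclared
predicate, a misspelled standard term (`owl:Classs`), an unsupported
construct, or a malformed structure aborts the whole translation with a
typed `MappingError`.  Axioms serialize deterministically to OWL 2
functional-style syntax.

## Worked example

Generate a small ontology with the built-in fixtures module and run the
stack over it:

```python
from owlstore.fixtures import OntologySpec, generate_document
gd = generate_document(OntologySpec(
    n_classes=3, n_object_properties=1, n_subclass_links=2,
    n_restrictions=1, n_annotations=1, seed=7))
open("example.owl", "w").write(gd.text)
```

```text
$ owlstore load example.owl
example.owl	http://example.org/onto/7	12 triples
total	IRI 5	Literal 1	Blank 1	Triples 12

$ owlstore axioms example.owl
Prefix(ns7:=<http://example.org/onto/7#>)
Prefix(owl:=<http://www.w3.org/2002/07/owl#>)
Prefix(rdf:=<http://www.w3.org/1999/02/22-rdf-syntax-ns#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)
Ontology(<http://example.org/onto/7>
Declaration(Class(ns7:C0))
Declaration(Class(ns7:C1))
Declaration(Class(ns7:C2))
Declaration(ObjectProperty(ns7:p0))
SubClassOf(ns7:C0 ObjectSomeValuesFrom(ns7:p0 ns7:C2))
SubClassOf(ns7:C1 ns7:C0)
SubClassOf(ns7:C1 ns7:C2)
AnnotationAssertion(rdfs:label ns7:C0 "class number 0 (note 0)")
9 axioms

$ owlstore validate example.owl
PASS	example.owl
```

The `load` line reports the document-derived term counts (5 IRIs: three
classes, one property, the ontology IRI; 1 literal: the label; 1 blank:
the restriction node) and the 12 triples.  The `axioms` output is the
functional-style rendering of the 9 axioms: the ontology header, four
declarations, three subclass axioms (one through an existential
restriction), and one annotation.  `owlstore query` answers triple
patterns from the shell, `owlstore catalog` prints a directory's ontology
catalog, and `owlstore bench` compares index configurations by the number
of element comparisons needed to answer a query workload.

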
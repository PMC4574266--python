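# Methods

This note records the model of the data, the procedures, the numerical
and design choices, and what the synthetic fixtures do and do not show.

## Data model

The store holds four object kinds behind opaque integer IDs:

- **Namespace IRIs** (`NsId`): an absolute IRI prefix.  An IRI is split
  into prefix + fragment at the last `#` if present, else the last `/`,
  else the last `:` (for `urn:`-style names).  Concatenation reconstructs
  the input exactly, so interning is lossless.
- **Terms** (`NodeId`): IRI nodes (prefix id + fragment), literal nodes,
  and blank nodes.  Literal identity is *value* identity under the
  datatype: the payload is parsed as bool / int / `Decimal` / float / str
  and canonicalized, so lexically different but value-equal literals share
  a node.  The interning key is `(datatype, canonical payload, language)`.
  Blank nodes carry `(document, ordinal)`; ordinals count up in first-seen
  order within a document, and labels are scoped per document, so blanks
  from different documents are always distinct.
- **Documents** (`DocId`): path (unique), ontology IRI, version IRI, and
  the import IRIs found in the header.  A document without an
  `owl:Ontology` header is registered with an absent ontology IRI.
- **Triples**: `(subject, predicate, object, document)` with no positional
  type restriction (a literal subject is representable; parsing never
  produces one).  Identity includes the document: the same `(s, p, o)`
  from two documents is stored twice, an exact duplicate within one
  document once.

The RDF/RDFS/OWL 2/XSD vocabulary (154 terms over 4 namespaces) is
pre-interned in a fixed enumeration order at store construction, making
term IDs compile-time-style constants: identical across stores,
configurations, and runs.  This also gives the mapper a crisp misspelling
test: any IRI in one of the four standard namespaces whose ID falls
outside the enumeration is a misspelled standard term.

## Indices and the query planner

An index layout is `bin key : sort order`, e.g. `s:pod`.  Bins are hash
buckets keyed by the binned term's ID; within a bin, triples are kept
sorted by the three sort-order terms (insertion by binary search).  The
default configuration is `s:pod` + `o:psd`, chosen because ontology
workloads are dominated by subject(+predicate) and object(+predicate)
lookups during axiom generation.  Index configuration is fixed at store
construction (idiomatic for a dynamic language; the contract — pay memory
only for the indices you want — is unchanged), and `reindexed()` produces
a content-identical store under a different configuration for studies.

For a pattern, the planner considers only indices whose bin key is
constrained and scores each by the length of the longest prefix of its
sort order consisting of constrained terms; the highest score wins, ties
broken by declaration order (deterministic).  The chosen bin is narrowed
by binary search on the prefix and filtered on any remaining constraints;
with no eligible index the store falls back to a filtered full scan.
Correctness is independent of configuration — the acceptance suite checks
result equality against a brute-force linear scan for all 16 constraint
combinations and across 1/2/4-index configurations.

Comparison counting (for the index study) counts element (ID)
comparisons: per binary-search probe, the number of tuple positions
examined; per scan candidate, the constrained positions checked until the
first mismatch.  This is a hardware-independent proxy for query cost; it
deliberately ignores constant factors, cache effects, and allocation.

## Loading and transactions

RDF/XML is parsed with `lxml` into an element tree and interpreted by a
recursive node-element / property-element walk covering the constructs
OWL documents use: typed nodes, `rdf:about`/`rdf:ID`/`rdf:nodeID`,
`rdf:resource`/`rdf:datatype`/`xml:lang`, property attributes, nested
nodes, `rdf:parseType` `Resource`/`Collection`/`Literal`, and scoped
`xml:base` with relative-IRI resolution.  `rdf:parseType="Literal"`
content is kept as a raw-serialization `rdf:XMLLiteral` string (full XML
canonicalization is out of scope).  Containers (`rdf:li`), reification
(`rdf:ID` on property elements), and unknown parse types are rejected —
they do not occur in OWL output and guessing would be silent
misinterpretation.  Plain literals are typed `xsd:string`, or
`rdf:langString` with a language tag.  Encodings are whatever the XML
declaration states and `lxml` supports (UTF-8/UTF-16 in practice).

Loading is transactional per top-level call.  A document is parsed to
statements, then validated (single `owl:Ontology` header; every typed
literal's lexical form parses under its datatype) before any store
mutation, so per-document failures are rejected without touching the
store.  The import closure adds a second layer: a checkpoint (table
sizes) is taken at the top-level `load`/`load_file`, and any failure
anywhere in the closure — including an unresolvable import IRI — rolls
everything back, so a failed call never leaves partial content.  Imports
are loaded depth-first in document order of the `owl:imports` triples,
each document at most once (tracked by ontology/version IRI and path),
which makes cycles terminate.  Import IRIs resolve through the catalog
only; remote fetching is deliberately unsupported.  Without a catalog,
imports are ignored with a logged warning.

The catalog scanner reads only each file's `owl:Ontology` header
(streaming parse, stopped at the header element's end), skips unparseable
or header-less files with a warning, and tries `.owl`/`.rdf`/`.xml` files
first.  Resolution prefers an exact version-IRI match, then an
ontology-IRI match — among several versions the lexicographically
greatest version IRI, a documented deterministic heuristic — then an
exact path match.

## Axiom mapping

Translation is strict and two-pass.  Pass one records declarations from
`(x, rdf:type, K)` triples with K in {`owl:Class`, `owl:ObjectProperty`,
`owl:DatatypeProperty`, `owl:AnnotationProperty`, `owl:NamedIndividual`,
`rdfs:Datatype`}.  Punning across Class/Individual/Datatype is allowed;
ObjectProperty + DatatypeProperty on one IRI is an error.  Built-ins
(`owl:Thing`, XSD datatypes, the standard annotation properties such as
`rdfs:label` and `owl:versionInfo`) need no declaration.

Pass two walks the remaining triples in document order.  Supported axiom
triggers: `rdfs:subClassOf`, `owl:equivalentClass`, `owl:disjointWith`,
`rdfs:subPropertyOf`/`rdfs:domain`/`rdfs:range` (dispatched on the
declared kind of the subject property), the Functional /
InverseFunctional / Transitive / Symmetric characteristics, class
assertions, object/data property assertions, annotation assertions, the
ontology header (version IRI, imports, header annotations), and reified
`owl:Axiom` annotation blocks, which are consumed and attached to their
target axiom.  Class expressions anchored at blank nodes cover
intersection/union/complement/enumeration and restrictions with exactly
one filler key (`someValuesFrom`, `allValuesFrom`, `hasValue`, plain and
qualified cardinalities); a blank may anchor at most one expression and
cycles are errors.  RDF lists are followed `rdf:first`/`rdf:rest` to
`rdf:nil` with branching, sharing, and cycles rejected.

Everything else in the OWL 2 vocabulary — property chains, `owl:hasKey`,
negative assertions, `owl:sameAs`/`differentFrom`, AllDifferent /
AllDisjoint lists, datatype restrictions — is *detected* and reported as
an unsupported construct rather than mis-mapped.  The accounting rule
that enforces completeness: every triple in scope must be consumed
exactly once (declaration, trigger, expression structure, list cell,
header, or annotation); leftovers abort.  All errors abort the whole
translation with a typed `MappingError` (`undeclared`, `misspelled`,
`unsupported`, `conflict`, `structure`), and no partial axiom list is
observable.

Serialization to functional-style syntax is deterministic: prefixes for
all used namespaces (fixed names for the four standard ones, short
derived names otherwise), declarations first, remaining axioms ordered by
kind then rendered text, and symmetric axioms (EquivalentClasses,
DisjointClasses) with sorted operands.  Import statements render inside
the `Ontology(...)` header, which counts as one axiom.

## Synthetic fixtures

`OntologySpec` generates an RDF/XML document with *n* classes, object
properties, subclass links, existential restrictions (via labeled blank
nodes), `rdfs:label` annotations, and import statements — deterministic
under its seed, with the expected statement and axiom multisets computed
in closed form (statements: `1 + imports + classes + properties + links +
4·restrictions + annotations`; axioms: `1 + classes + properties + links
+ restrictions + annotations`).  Error-injected variants break exactly
one stage: truncated XML (`xml`), a reused `rdf:ID` (`rdf`), a duplicate
ontology header (`owl`, load time), an undeclared predicate or a
misspelled `owl:Classs` (strict mapping time).  Default sizes (10
classes, 2 properties, 5 links, 2 restrictions, 3 annotations) mirror the
shape of a small OBO-style module: a class hierarchy with a sprinkling of
existential restrictions and label annotations.

What the fixtures do *not* emulate: the statistical profile of any
specific large ontology (term/triple ratios, deep nesting of boolean
expressions, axiom-level annotation density), datatype variety beyond
strings and the XSD numeric family, or multi-megabyte documents.  Passing
tests therefore demonstrate correctness of the mapping and the store
contracts, not loading throughput on real corpora.

The query workload generator mirrors the classic triple-store benchmark —
a random subject with the constant predicate `rdfs:subClassOf` — plus a
uniform sweep over all 16 constraint combinations for oracle tests.
Random stores draw triples over a bounded ID universe (subjects/objects
scaled to a tenth of the triple count) so typical patterns match several
triples.

## Index study

The study re-bins identical content under each configuration in a design
space of all four bin choices with two sort orders each, plus the default
two-index configuration, and answers the same workload while counting
element comparisons; identical result multisets across configurations are
asserted as a side effect.  On the subject+`rdfs:subClassOf` workload
over 10,000 triples, the default configuration needs on the order of a
thousand times fewer comparisons than a configuration that cannot serve
the pattern (full scan) — the direction and rough magnitude of the
benefit of matching indices to the axiom-generation access pattern.  The
acceptance script reports the measured ratio; wall-clock rates are
hardware-dependent and are not measured.

## Numerical and edge-case choices

- XSD boolean accepts `true/false/1/0`; the integer family is
  range-checked per subtype; `decimal` uses `decimal.Decimal` (non-finite
  rejected); `float`/`double` accept `INF`/`-INF`/`NaN` with `NaN`
  canonicalized so value-equal literals share a node.  Unknown datatypes
  fall back to raw-lexical identity.
- Cardinality literals must parse as non-negative integers (any XSD
  integer type); negatives and non-integers are structure errors.
- Problem sizes in tests and the acceptance script (20 stores of 10,000
  triples, 100 generator specs, 30 error-injected loads, 25
  oracle-compared documents) were chosen to exercise every code path with
  multi-triple bins and non-trivial import graphs while keeping the suite
  comfortably interactive.
- Concurrency contract: read-only operations may be interleaved; any
  mutation requires exclusive access.  No locks are provided.

## Known limitations

- Input is RDF/XML only; no serialization back to RDF/XML and no
  Turtle/OWL-XML/Manchester syntaxes.
- The supported axiom subset covers common OBO-family constructs; the
  full OWL 2 mapping (chains, keys, negative assertions, facets) is
  detected-and-rejected, not translated.
- No reasoning, no SPARQL, no triple deletion, no persistence.
- `rdf:XMLLiteral` content is compared by raw serialization, not
  exclusive canonicalization.
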
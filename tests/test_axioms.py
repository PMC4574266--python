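"""Axiom mapper tests: declarations, RDF lists, class expressions, the
strict error taxonomy, serialization, and agreement with an independent
rdflib-based oracle on whole documents."""

import pytest

from owlstore import (
    MappingError,
    TripleStore,
    collect_declarations,
    load,
    map_axioms,
    parse_rdf_list,
    serialize_functional,
)
from owlstore import vocabulary as voc
from owlstore.fixtures import OntologySpec, generate_document

from helpers import package_axioms_to_tuples
from owl_oracle import oracle_axioms

HEAD = (
    '<?xml version="1.0"?>\n'
    '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
    '         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"\n'
    '         xmlns:owl="http://www.w3.org/2002/07/owl#"\n'
    '         xmlns:xsd="http://www.w3.org/2001/XMLSchema#"\n'
    '         xmlns:ex="http://ex.org/x#">\n'
)


def load_doc(body: str) -> tuple:
    store = TripleStore()
    doc = load(
        store, HEAD + body + "\n</rdf:RDF>\n", "http://ex.org/doc",
        path="mem://doc",
    )
    return store, doc


def axioms_of(body: str):
    store, doc = load_doc(body)
    return store, map_axioms(store, doc)


class TestDeclarations:
    def test_class_declaration_recorded(self):
        store, doc = load_doc('<owl:Class rdf:about="http://ex.org/x#A"/>')
        decls = collect_declarations(store, store.triples)
        a = store.lookup_iri("http://ex.org/x#A")
        assert decls.has(a, "Class")

    def test_object_vs_data_property_conflict(self):
        store, doc = load_doc(
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:DatatypeProperty rdf:about="http://ex.org/x#p"/>'
        )
        with pytest.raises(MappingError) as err:
            collect_declarations(store, store.triples)
        assert err.value.kind == "conflict"
        assert "p" in str(err.value)

    def test_punning_class_and_individual_allowed(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:NamedIndividual rdf:about="http://ex.org/x#A"/>'
        )
        kinds = sorted(
            a.operands[0] for a in axioms if a.kind == "Declaration"
        )
        assert kinds == ["Class", "NamedIndividual"]

    def test_declaration_count_by_construction(self):
        body = "".join(
            f'<owl:Class rdf:about="http://ex.org/x#C{i}"/>' for i in range(5)
        ) + "".join(
            f'<owl:ObjectProperty rdf:about="http://ex.org/x#p{i}"/>'
            for i in range(2)
        )
        _, axioms = axioms_of(body)
        assert sum(a.kind == "Declaration" for a in axioms) == 7


class TestRdfLists:
    def test_nil_head_is_empty_list(self, store):
        assert parse_rdf_list(store, voc.RDF_NIL) == []

    def test_three_member_list_in_order(self, store):
        d = store.add_doc("mem://d")
        members = [store.intern_iri(f"http://ex.org/m{i}") for i in range(3)]
        heads = [store.make_blank(d, f"l{i}") for i in range(3)]
        for i, h in enumerate(heads):
            store.add_triple(h, voc.RDF_FIRST, members[i], d)
            nxt = heads[i + 1] if i + 1 < 3 else voc.RDF_NIL
            store.add_triple(h, voc.RDF_REST, nxt, d)
        assert parse_rdf_list(store, heads[0]) == members

    def test_branching_rest_is_error(self, store):
        d = store.add_doc("mem://d")
        h = store.make_blank(d, "h")
        m = store.intern_iri("http://ex.org/m")
        store.add_triple(h, voc.RDF_FIRST, m, d)
        store.add_triple(h, voc.RDF_REST, voc.RDF_NIL, d)
        store.add_triple(h, voc.RDF_REST, h, d)
        with pytest.raises(MappingError) as err:
            parse_rdf_list(store, h)
        assert err.value.kind == "structure"

    def test_cycle_is_error(self, store):
        d = store.add_doc("mem://d")
        h = store.make_blank(d, "h")
        m = store.intern_iri("http://ex.org/m")
        store.add_triple(h, voc.RDF_FIRST, m, d)
        store.add_triple(h, voc.RDF_REST, h, d)
        with pytest.raises(MappingError):
            parse_rdf_list(store, h)


class TestClassExpressions:
    def test_intersection_of_declared_classes(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#B"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<owl:equivalentClass><owl:Class>'
            '<owl:intersectionOf rdf:parseType="Collection">'
            '<rdf:Description rdf:about="http://ex.org/x#A"/>'
            '<rdf:Description rdf:about="http://ex.org/x#B"/>'
            '</owl:intersectionOf></owl:Class></owl:equivalentClass>'
            '</owl:Class>'
        )
        eq = [a for a in axioms if a.kind == "EquivalentClasses"]
        assert len(eq) == 1
        kinds = sorted(ce.kind for ce in eq[0].operands)
        assert kinds == ["and", "named"]

    def test_existential_restriction(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#B"/>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<rdfs:subClassOf><owl:Restriction>'
            '<owl:onProperty rdf:resource="http://ex.org/x#p"/>'
            '<owl:someValuesFrom rdf:resource="http://ex.org/x#A"/>'
            '</owl:Restriction></rdfs:subClassOf></owl:Class>'
        )
        sub = [a for a in axioms if a.kind == "SubClassOf"]
        assert len(sub) == 1
        sup = sub[0].operands[1]
        assert sup.kind == "some" and not sup.data
        text = serialize_functional(axioms, store)
        assert "ObjectSomeValuesFrom(x:p x:A)" in text

    def test_qualified_cardinality(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<rdfs:subClassOf><owl:Restriction>'
            '<owl:onProperty rdf:resource="http://ex.org/x#p"/>'
            '<owl:qualifiedCardinality rdf:datatype='
            '"http://www.w3.org/2001/XMLSchema#nonNegativeInteger">2'
            '</owl:qualifiedCardinality>'
            '<owl:onClass rdf:resource="http://ex.org/x#A"/>'
            '</owl:Restriction></rdfs:subClassOf></owl:Class>'
        )
        text = serialize_functional(axioms, store)
        assert "ObjectExactCardinality(2 x:p x:A)" in text

    def test_restriction_without_on_property_is_error(self):
        store, doc = load_doc(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<rdfs:subClassOf><owl:Restriction>'
            '<owl:someValuesFrom rdf:resource="http://ex.org/x#A"/>'
            '</owl:Restriction></rdfs:subClassOf></owl:Class>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert "onProperty" in str(err.value)

    def test_restriction_with_two_filler_keys_is_error(self):
        store, doc = load_doc(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<rdfs:subClassOf><owl:Restriction>'
            '<owl:onProperty rdf:resource="http://ex.org/x#p"/>'
            '<owl:someValuesFrom rdf:resource="http://ex.org/x#A"/>'
            '<owl:allValuesFrom rdf:resource="http://ex.org/x#A"/>'
            '</owl:Restriction></rdfs:subClassOf></owl:Class>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert err.value.kind == "structure"

    def test_negative_cardinality_is_error(self):
        store, doc = load_doc(
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<rdfs:subClassOf><owl:Restriction>'
            '<owl:onProperty rdf:resource="http://ex.org/x#p"/>'
            '<owl:minCardinality rdf:datatype='
            '"http://www.w3.org/2001/XMLSchema#integer">-1'
            '</owl:minCardinality>'
            '</owl:Restriction></rdfs:subClassOf></owl:Class>'
        )
        with pytest.raises(MappingError):
            map_axioms(store, doc)

    def test_undeclared_named_class_in_expression_is_error(self):
        store, doc = load_doc(
            '<owl:Class rdf:about="http://ex.org/x#A">'
            '<rdfs:subClassOf rdf:resource="http://ex.org/x#Nowhere"/>'
            '</owl:Class>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert err.value.kind == "undeclared"


class TestErrorTaxonomy:
    def test_undeclared_predicate_named_in_error(self):
        store, doc = load_doc(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<rdf:Description rdf:about="http://ex.org/x#A">'
            '<ex:partOf rdf:resource="http://ex.org/x#A"/>'
            '</rdf:Description>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert err.value.kind == "undeclared"
        assert "partOf" in str(err.value)

    def test_misspelled_standard_term_detected(self):
        store, doc = load_doc(
            '<rdf:Description rdf:about="http://ex.org/x#A">'
            '<rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Classs"/>'
            '</rdf:Description>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert err.value.kind == "misspelled"
        assert "Classs" in str(err.value)

    def test_unsupported_construct_reported_not_mismapped(self):
        store, doc = load_doc(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#B"/>'
            '<rdf:Description rdf:about="http://ex.org/x#A">'
            '<owl:sameAs rdf:resource="http://ex.org/x#B"/>'
            '</rdf:Description>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert err.value.kind == "unsupported"

    def test_abort_yields_no_partial_output(self):
        # the valid half alone maps fine; with the bad triple appended the
        # translation must fail as a whole
        good = '<owl:Class rdf:about="http://ex.org/x#A"/>'
        bad = (
            '<rdf:Description rdf:about="http://ex.org/x#A">'
            '<ex:broken rdf:resource="http://ex.org/x#A"/>'
            '</rdf:Description>'
        )
        store, axioms = axioms_of(good)
        assert axioms
        store2, doc2 = load_doc(good + bad)
        with pytest.raises(MappingError):
            map_axioms(store2, doc2)

    def test_leftover_triples_are_an_error(self):
        # an orphan restriction referenced by nothing must not be dropped
        store, doc = load_doc(
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<rdf:Description rdf:nodeID="orphan">'
            '<rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Restriction"/>'
            '<owl:onProperty rdf:resource="http://ex.org/x#p"/>'
            '<owl:someValuesFrom rdf:resource="http://ex.org/x#A"/>'
            '</rdf:Description>'
        )
        with pytest.raises(MappingError) as err:
            map_axioms(store, doc)
        assert err.value.kind == "structure"


class TestStrictnessMonotonicity:
    BODY = (
        '<owl:Class rdf:about="http://ex.org/x#A"/>'
        '<rdf:Description rdf:about="http://ex.org/x#A">'
        '<ex:rel rdf:resource="http://ex.org/x#A"/>'
        '</rdf:Description>'
    )
    DECL = '<owl:ObjectProperty rdf:about="http://ex.org/x#rel"/>'

    def test_adding_declaration_fixes_undeclared_error(self):
        store, doc = load_doc(self.BODY)
        with pytest.raises(MappingError):
            map_axioms(store, doc)
        store2, doc2 = load_doc(self.DECL + self.BODY)
        axioms = map_axioms(store2, doc2)
        assert any(a.kind == "ObjectPropertyAssertion" for a in axioms)


class TestAxiomKinds:
    def test_property_axioms_and_characteristics(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p">'
            '<rdfs:domain rdf:resource="http://ex.org/x#A"/>'
            '<rdfs:range rdf:resource="http://ex.org/x#A"/>'
            '<rdf:type rdf:resource='
            '"http://www.w3.org/2002/07/owl#TransitiveProperty"/>'
            '</owl:ObjectProperty>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#q">'
            '<rdfs:subPropertyOf rdf:resource="http://ex.org/x#p"/>'
            '</owl:ObjectProperty>'
        )
        kinds = sorted(a.kind for a in axioms if a.kind != "Declaration")
        assert kinds == [
            "ObjectPropertyDomain", "ObjectPropertyRange",
            "SubObjectPropertyOf", "TransitiveObjectProperty",
        ]

    def test_assertions(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:DatatypeProperty rdf:about="http://ex.org/x#d"/>'
            '<owl:NamedIndividual rdf:about="http://ex.org/x#i">'
            '<rdf:type rdf:resource="http://ex.org/x#A"/>'
            '<ex:p rdf:resource="http://ex.org/x#j"/>'
            '<ex:d rdf:datatype="http://www.w3.org/2001/XMLSchema#int">7</ex:d>'
            '</owl:NamedIndividual>'
            '<owl:NamedIndividual rdf:about="http://ex.org/x#j"/>'
        )
        kinds = sorted(a.kind for a in axioms if a.kind != "Declaration")
        assert kinds == [
            "ClassAssertion", "DataPropertyAssertion",
            "ObjectPropertyAssertion",
        ]

    def test_reified_axiom_annotation_attached(self):
        store, axioms = axioms_of(
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#B"/>'
            '<rdf:Description rdf:about="http://ex.org/x#A">'
            '<rdfs:subClassOf rdf:resource="http://ex.org/x#B"/>'
            '</rdf:Description>'
            '<owl:Axiom>'
            '<owl:annotatedSource rdf:resource="http://ex.org/x#A"/>'
            '<owl:annotatedProperty rdf:resource='
            '"http://www.w3.org/2000/01/rdf-schema#subClassOf"/>'
            '<owl:annotatedTarget rdf:resource="http://ex.org/x#B"/>'
            '<rdfs:comment>evidence</rdfs:comment>'
            '</owl:Axiom>'
        )
        sub = [a for a in axioms if a.kind == "SubClassOf"]
        assert len(sub) == 1
        assert len(sub[0].annotations) == 1
        text = serialize_functional(axioms, store)
        assert 'SubClassOf(Annotation(rdfs:comment "evidence") x:A x:B)' \
            in text


class TestSerialization:
    def test_empty_ontology_serializes_header_only(self):
        store, axioms = axioms_of(
            '<owl:Ontology rdf:about="http://ex.org/onto"/>'
        )
        assert len(axioms) == 1
        text = serialize_functional(axioms, store)
        assert "Ontology(<http://ex.org/onto>" in text
        assert text.count("\n") < 10

    def test_serialization_is_deterministic(self, loaded_fixture):
        store, doc, gd = loaded_fixture
        t1 = serialize_functional(map_axioms(store, doc), store)
        t2 = serialize_functional(map_axioms(store, doc), store)
        assert t1 == t2

    def test_prefixes_declared_for_used_namespaces(self, loaded_fixture):
        store, doc, gd = loaded_fixture
        text = serialize_functional(map_axioms(store, doc), store)
        assert f"=<{gd.spec.entity_ns}>" in text


class TestOracleAgreement:
    """Whole-document agreement with an independent rdflib-based mapping."""

    BODIES = [
        (
            '<owl:Ontology rdf:about="http://ex.org/onto"/>'
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#B">'
            '<rdfs:subClassOf rdf:resource="http://ex.org/x#A"/>'
            '<owl:disjointWith rdf:resource="http://ex.org/x#A"/>'
            '</owl:Class>'
        ),
        (
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:Class rdf:about="http://ex.org/x#B"/>'
            '<owl:ObjectProperty rdf:about="http://ex.org/x#p"/>'
            '<owl:Class rdf:about="http://ex.org/x#C">'
            '<owl:equivalentClass><owl:Class>'
            '<owl:unionOf rdf:parseType="Collection">'
            '<rdf:Description rdf:about="http://ex.org/x#A"/>'
            '<rdf:Description rdf:about="http://ex.org/x#B"/>'
            '</owl:unionOf></owl:Class></owl:equivalentClass>'
            '<rdfs:subClassOf><owl:Restriction>'
            '<owl:onProperty rdf:resource="http://ex.org/x#p"/>'
            '<owl:allValuesFrom rdf:resource="http://ex.org/x#B"/>'
            '</owl:Restriction></rdfs:subClassOf></owl:Class>'
        ),
        (
            '<owl:Class rdf:about="http://ex.org/x#A"/>'
            '<owl:DatatypeProperty rdf:about="http://ex.org/x#d">'
            '<rdfs:domain rdf:resource="http://ex.org/x#A"/>'
            '<rdfs:range rdf:resource='
            '"http://www.w3.org/2001/XMLSchema#int"/>'
            '</owl:DatatypeProperty>'
            '<owl:NamedIndividual rdf:about="http://ex.org/x#i">'
            '<rdf:type rdf:resource="http://ex.org/x#A"/>'
            '<ex:d rdf:datatype="http://www.w3.org/2001/XMLSchema#int">3'
            '</ex:d><rdfs:label xml:lang="en">thing</rdfs:label>'
            '</owl:NamedIndividual>'
        ),
    ]

    @pytest.mark.parametrize("body", BODIES)
    def test_hand_written_documents_agree(self, body):
        text = HEAD + body + "\n</rdf:RDF>\n"
        store = TripleStore()
        doc = load(store, text, "http://example.org/base", path="mem://o")
        ours = package_axioms_to_tuples(store, map_axioms(store, doc))
        theirs = oracle_axioms(text)
        assert ours == theirs

    @pytest.mark.parametrize("seed", range(6))
    def test_generated_documents_agree(self, seed):
        spec = OntologySpec(
            n_classes=6, n_object_properties=2, n_subclass_links=5,
            n_restrictions=3, n_annotations=3, seed=200 + seed,
        )
        gd = generate_document(spec)
        store = TripleStore()
        doc = load(store, gd.text, "http://example.org/base", path="mem://g")
        ours = package_axioms_to_tuples(store, map_axioms(store, doc))
        theirs = oracle_axioms(gd.text)
        assert ours == theirs
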
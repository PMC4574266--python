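import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from owlstore import TripleStore, load
from owlstore.fixtures import OntologySpec, generate_document


@pytest.fixture
def store():
    """A fresh store with the default two-index configuration."""
    return TripleStore()


@pytest.fixture
def loaded_fixture():
    """A small valid generated ontology loaded into a fresh store."""
    spec = OntologySpec(
        n_classes=6, n_object_properties=2, n_subclass_links=4,
        n_restrictions=2, n_annotations=2, seed=11,
    )
    gd = generate_document(spec)
    store = TripleStore()
    doc = load(store, gd.text, "http://example.org/base", path="mem://fixture")
    return store, doc, gd
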
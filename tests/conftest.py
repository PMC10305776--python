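import pytest

from strokener.embeddings import HashEmbeddings
from strokener.ontology import load_default_ontology
from strokener.simulate import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def ontology():
    return load_default_ontology()


@pytest.fixture(scope="session")
def small_corpus():
    """Small default-ontology corpus shared by read-only tests."""
    return generate_corpus(CorpusConfig(seed=42, n_patients=60, total_spans=1200))


@pytest.fixture(scope="session")
def hash_embeddings():
    return HashEmbeddings()
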
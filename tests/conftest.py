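import pytest

from dictmap.dictionary_model import ElementMetadata, MetadataStore
from dictmap.pipeline import MappingPipeline, PipelineConfig
from dictmap.synthetic_data import GeneratorConfig, generate_pair


def element(source, name, table="t", short="", long="", **kw) -> ElementMetadata:
    return ElementMetadata(
        source_id=source,
        element_name=name,
        table_name=table,
        short_description=short,
        long_description=long,
        **kw,
    )


@pytest.fixture(scope="session")
def toy_corpus_store():
    """Three-document corpus with hand-enumerable vocabulary."""
    return MetadataStore(
        [
            element("a", "E1", short="memory recall score"),
            element("b", "F1", short="memory score total"),
            element("b", "F2", short="blood pressure reading"),
        ]
    )


SMALL_GEN = GeneratorConfig(
    n_concepts=30, n_distractors_per_source=40, n_tables=4, seed=7
)


@pytest.fixture(scope="session")
def small_pair():
    """A modest generated dictionary pair shared by integration tests."""
    storeS, storeT, truth = generate_pair(SMALL_GEN)
    return storeS, storeT, truth


@pytest.fixture(scope="session")
def small_pipeline(small_pair):
    storeS, storeT, _ = small_pair
    store = storeS.merge(storeT)
    return MappingPipeline(store, SMALL_GEN.source_ids, PipelineConfig(seed=7)).fit()
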
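import pytest

from impo import apply_mappings, build_core_schema, default_mapping_set, \
    generate_bundle


@pytest.fixture(scope="session")
def core_schema():
    return build_core_schema()


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle()


@pytest.fixture(scope="session")
def default_graph(default_bundle):
    # note: instancing registers punned gene class facets, so the graph
    # gets its own schema instance rather than the shared fixture
    return apply_mappings(default_bundle.tables, default_mapping_set(),
                          build_core_schema())
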
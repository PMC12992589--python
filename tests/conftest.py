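import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from wormflux.fixtures import (  # noqa: E402
    make_core_energy_model,
    make_mapping_fixture,
    make_template_pair,
    make_ump_fixture,
)


@pytest.fixture(scope="session")
def core_bundle():
    """Refined full core-energy fixture (with biosynthesis and answer key)."""
    return make_core_energy_model()


@pytest.fixture(scope="session")
def small_core_bundle():
    """Core energetics without biosynthesis: < 50 reactions, oracle-sized."""
    return make_core_energy_model(include_biosynthesis=False)


@pytest.fixture(scope="session")
def raw_core_bundle():
    """Pre-refinement core fixture (reversible hydrolases/decarboxylase)."""
    return make_core_energy_model(refined=False)


@pytest.fixture
def core_model(core_bundle):
    return core_bundle.models["core_energy"].copy()


@pytest.fixture
def small_core_model(small_core_bundle):
    return small_core_bundle.models["core_energy"].copy()


@pytest.fixture
def raw_core_model(raw_core_bundle):
    return raw_core_bundle.models["core_energy"].copy()


@pytest.fixture(scope="session")
def ump_bundle():
    return make_ump_fixture()


@pytest.fixture
def ump_model(ump_bundle):
    return ump_bundle.models["ump_pathway"].copy()


@pytest.fixture(scope="session")
def template_pair_bundle():
    return make_template_pair(seed=0)


@pytest.fixture(scope="session")
def mapping_bundle():
    return make_mapping_fixture(12, 3, seed=1)


@pytest.fixture(scope="session")
def template_pair_matches(template_pair_bundle):
    """Graph + metabolite + reaction matches for the template pair."""
    from wormflux import xref

    tp = template_pair_bundle
    graph = xref.build_xref_graph(
        "biocyc",
        "bigg",
        direct_links=tp.tables["direct_links"],
        bridge_tables=[tp.tables["bridge_metanetx"]],
        third_party_annotations=tp.specs["annotations"],
    )
    source = tp.models["flat_source"]
    template = tp.models["template"]
    met_matches = xref.match_metabolites(source, template, graph)
    rxn_matches = xref.match_reactions(source, template, met_matches)
    return graph, met_matches, rxn_matches
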
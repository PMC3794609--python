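import pytest

from tissueranker import PlantingSpec, generate_fixture


@pytest.fixture(scope="session")
def default_spec():
    return PlantingSpec(seed=0)


@pytest.fixture(scope="session")
def planted_fixture(default_spec):
    """Default synthetic fixture: (network, compendium, gold, category map)."""
    return generate_fixture(default_spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_spec):
    """Default fixture written to disk in the TSV formats the readers consume."""
    from tissueranker import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(default_spec, outdir)
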
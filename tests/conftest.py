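import pytest

from enzselect import load_database, run_query
from enzselect.fixtures import FixtureSpec, generate_fixture
from enzselect.pipeline import QueryRequest

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_spec):
    out = tmp_path_factory.mktemp("fixture_db")
    generate_fixture(fixture_spec, out)
    return out


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    import json

    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def db(fixture_dir):
    return load_database(fixture_dir)


@pytest.fixture(scope="session")
def pal_request(manifest):
    return QueryRequest(
        host=manifest["host_taxon"],
        smiles=manifest["pal_query_smiles"],
        targets=20,
    )


@pytest.fixture(scope="session")
def pal_result(pal_request, db):
    return run_query(pal_request, db)
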
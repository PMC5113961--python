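import pytest

from corecazyome.synthetic import CommunityConfig, generate_community, write_fixture


@pytest.fixture(scope="session")
def small_config():
    return CommunityConfig(n_samples=4, n_contigs=300, core_fraction=0.1, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    manifest = write_fixture(small_truth, out)
    return out, manifest
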
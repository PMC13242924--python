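import warnings

import pytest

import h5adkit as hk


@pytest.fixture(autouse=True)
def _silence_expected_conversion_warnings():
    """Stash/coercion warnings are part of the converters' contract and
    fire constantly on the corpus; tests that care assert them with
    pytest.warns explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def corpus_specs():
    return hk.corpus()


@pytest.fixture(scope="session")
def corpus_containers(corpus_specs):
    return {name: hk.generate(spec) for name, spec in corpus_specs}


@pytest.fixture(scope="session")
def corpus_files(tmp_path_factory, corpus_containers):
    """Every corpus fixture written once to disk (session-scoped; tests
    must not mutate these files — copy first)."""
    d = tmp_path_factory.mktemp("corpus")
    paths = {}
    for name, adata in corpus_containers.items():
        p = d / f"{name}.h5ad"
        hk.write_h5ad(adata, p)
        paths[name] = p
    return paths
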
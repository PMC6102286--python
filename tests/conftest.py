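import pytest

import statinsig as ss


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: 300 genes, 20 planted, EA 25/25 + 20 background, AA 12/14."""
    return ss.SimulationConfig(n_genes=300, n_signature=20,
                               n_background_samples=20, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return ss.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_delta(small_study):
    from statinsig.pipeline import prepare_delta
    e = small_study.expression
    return prepare_delta(e.statin, e.control, small_study.phenotypes)


@pytest.fixture(scope="session")
def ea_labels(small_study):
    from statinsig.pipeline import _labels
    return _labels(small_study.phenotypes, "EA")


@pytest.fixture(scope="session")
def aa_labels(small_study):
    from statinsig.pipeline import _labels
    return _labels(small_study.phenotypes, "AA")
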
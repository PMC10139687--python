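import pytest

from vapexposure import synth
from vapexposure.preprocess import preprocess_corpus


@pytest.fixture(scope="session")
def small_config():
    """A reduced design: full 16-profile cohort, 3 terms, 2 pages."""
    return synth.GeneratorConfig(seed=7, n_terms=3, pages=2)


@pytest.fixture(scope="session")
def cohort(small_config):
    return synth.generate_profile_cohort(small_config)


@pytest.fixture(scope="session")
def pool(small_config):
    return synth.generate_video_pool(small_config, 300)


@pytest.fixture(scope="session")
def results(small_config, cohort, pool):
    return synth.simulate_search_results(pool, cohort, small_config)


@pytest.fixture(scope="session")
def corpus(pool):
    return preprocess_corpus(pool)
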
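"""Shared fixtures: one small synthetic bundle and embedding artefacts.

The expensive artefacts (trained model, 3-member ensemble) are session-scoped
and built on a deliberately small study so the whole suite stays fast.
"""

import pytest

import dismol as dm


@pytest.fixture(scope="session")
def small_config():
    return dm.GenerationConfig(n_patients=60, rng_seed=3)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return dm.generate_bundle(small_config)


@pytest.fixture(scope="session")
def model_config():
    return dm.GenerationConfig(n_patients=120, rng_seed=5)


@pytest.fixture(scope="session")
def model_bundle(model_config):
    return dm.generate_bundle(model_config)


@pytest.fixture(scope="session")
def model_corpus(model_bundle):
    return dm.corpus_stats(dm.select_sections(e) for e in model_bundle.encounters)


@pytest.fixture(scope="session")
def trained_model(model_corpus):
    cfg = dm.TrainConfig(dim=30, window=4, min_count=3, epochs=3, seed=1)
    return dm.train_embedding(model_corpus, cfg)


@pytest.fixture(scope="session")
def small_ensemble(model_corpus):
    cfg = dm.TrainConfig(dim=30, window=4, min_count=3, epochs=3)
    return dm.build_ensemble(model_corpus, cfg, n_models=3, base_seed=10)
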
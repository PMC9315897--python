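import pytest

from depehr import (
    SimConfig,
    default_lexicon,
    emit_negation_corpus,
    generate_cohort,
    train_tagger,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """200 patients with misspellings and negated decoys."""
    cfg = SimConfig(n_patients=200, seed=101, misspelling_rate=0.2)
    patients, truth = generate_cohort(cfg)
    return cfg, patients, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no misspellings."""
    cfg = SimConfig(n_patients=200, seed=202, misspelling_rate=0.0)
    patients, truth = generate_cohort(cfg)
    return cfg, patients, truth


@pytest.fixture(scope="session")
def negation_corpus():
    """Default-size bilingual annotated corpus (572 es / 277 ca) with a
    70/30 train/held-out split."""
    cfg = SimConfig(n_patients=700, seed=11, negation_rate=0.35)
    _, truth = generate_cohort(cfg)
    return emit_negation_corpus(truth, seed=5)


@pytest.fixture(scope="session")
def trained_tagger(negation_corpus):
    train, _ = negation_corpus
    return train_tagger(train, seed=5)
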
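"""Shared fixtures: the worked-example sentence and small synthetic corpora."""

import numpy as np
import pytest

from entrotext.synthetic import (
    ClassProfile,
    SyntheticCorpusSpec,
    default_profiles,
    generate_corpus,
)

#: 22-word example sentence used for hand-checkable entropy arithmetic.
EXAMPLE_SENTENCE = (
    "The two sides will hold the first meeting of the China–U.S. "
    "intergovernmental dialogue on artificial intelligence, and continue "
    "various other exchange mechanisms."
)

#: Coarse POS sequence of the example sentence (one tag per word token).
EXAMPLE_TAGS = (
    "Det Num Noun Aux Verb Det Adj Noun Prep Det Noun Adj Noun Prep Adj "
    "Noun Conj Verb Adj Adj Noun Noun"
).split()

#: Strict plug-in entropies of the example sentence, frozen from an
#: independent per-type summation oracle (see test_features).
EXAMPLE_WORD_H1 = 4.243300368538955
EXAMPLE_POS_H1 = 2.640521962682592


@pytest.fixture
def example_tagger():
    """Deterministic fixture tagger returning the printed tag sequence."""

    def tag(tokens):
        assert len(tokens) == len(EXAMPLE_TAGS)
        return list(EXAMPLE_TAGS)

    return tag


@pytest.fixture(scope="session")
def small_corpus():
    """Three-class corpus at reduced size (30 texts x 200 tokens)."""
    profiles = default_profiles(n_texts=30, text_length=200)
    return generate_corpus(SyntheticCorpusSpec(profiles=profiles, seed=42))


@pytest.fixture(scope="session")
def small_table(small_corpus):
    from entrotext.features import build_feature_table

    return build_feature_table(small_corpus)


@pytest.fixture
def simple_profile():
    """A minimal valid profile for operation-level tests."""
    return ClassProfile(
        label="X",
        vocab_size=22,
        zipf_exponent=0.0,
        pos_templates=((("Det", "Noun", "Verb"), 1.0),),
        template_noise=0.0,
        text_length=50,
        n_texts=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
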
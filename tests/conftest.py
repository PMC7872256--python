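import numpy as np
import pytest

from bionerst import (
    Corpus,
    LabelSource,
    Sentence,
    SynthConfig,
    TaggerConfig,
    Vocabulary,
    generate_corpus,
    make_lexicons,
)


@pytest.fixture(scope="session")
def micro_config() -> TaggerConfig:
    """Tiny tagger for fast structural tests (not meant to learn well)."""
    return TaggerConfig(
        embed_dim=12,
        hidden_units=10,
        recurrent_layers=2,
        batch_size=16,
        learning_rate=2e-2,
        max_epochs=4,
        patience=10,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_synth() -> SynthConfig:
    return SynthConfig(
        background_vocab_size=60,
        source_lexicon_size=30,
        target_lexicon_size=20,
        lexicon_overlap=0.5,
        entity_density=0.12,
        sentence_length_range=(5, 10),
        n_sentences=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_synth) -> Corpus:
    _, target_lex = make_lexicons(small_synth)
    return generate_corpus(target_lex, small_synth, "small")


@pytest.fixture(scope="session")
def small_vocab(small_corpus) -> Vocabulary:
    return Vocabulary.build(small_corpus)


def hand_sentences() -> list[Sentence]:
    return [
        Sentence("c:0", ("a", "b", "c"), ("B", "I", "O"), LabelSource.GOLD),
        Sentence("c:1", ("d", "e"), ("O", "B"), LabelSource.GOLD),
        Sentence("c:2", ("a", "c", "e", "b"), ("O", "O", "B", "I"), LabelSource.GOLD),
    ]


@pytest.fixture
def hand_corpus() -> Corpus:
    return Corpus(hand_sentences(), name="c")


def random_bio(rng: np.random.Generator, n: int) -> list[str]:
    """Random valid BIO sequence (no orphan I)."""
    labels = []
    prev_entity = False
    for _ in range(n):
        if prev_entity:
            lab = rng.choice(["B", "I", "O"], p=[0.2, 0.4, 0.4])
        else:
            lab = rng.choice(["B", "O"], p=[0.3, 0.7])
        labels.append(str(lab))
        prev_entity = lab in ("B", "I")
    return labels
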
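"""Corpus data model, CoNLL round trips, BIO/span conversion, splitting."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from bionerst import (
    Corpus,
    CorpusFormatError,
    EntitySpan,
    LabelSource,
    Sentence,
    SplitSpec,
    parse_bio,
    read_conll,
    spans_to_bio,
    split_corpus,
    write_conll,
)

from conftest import random_bio


# -- sentence / span validity ------------------------------------------------


def test_sentence_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        Sentence("s", ())
    with pytest.raises(ValueError):
        Sentence("s", ("a", "b"), ("B",), LabelSource.GOLD)
    with pytest.raises(ValueError):
        Sentence("s", ("a",), ("X",), LabelSource.GOLD)
    with pytest.raises(ValueError):
        EntitySpan(2, 2)


def test_corpus_rejects_duplicate_ids():
    s = Sentence("x", ("a",))
    with pytest.raises(ValueError, match="duplicate"):
        Corpus([s, s])


# -- CoNLL I/O ---------------------------------------------------------------


def test_read_conll_two_sentence_fixture(tmp_path):
    path = tmp_path / "two.conll"
    path.write_text("a\tB\nb\tI\n\nc\tO\n")
    corpus = read_conll(path)
    assert len(corpus) == 2
    assert corpus[0].tokens == ("a", "b") and corpus[0].labels == ("B", "I")
    assert corpus[1].tokens == ("c",) and corpus[1].labels == ("O",)
    assert all(s.label_source == LabelSource.GOLD for s in corpus)


def test_read_conll_empty_file(tmp_path):
    path = tmp_path / "empty.conll"
    path.write_text("")
    assert len(read_conll(path)) == 0


def test_read_conll_unlabeled_dialect(tmp_path):
    path = tmp_path / "u.conll"
    path.write_text("a\nb\n\nc\n")
    corpus = read_conll(path)
    assert corpus[0].labels is None
    assert corpus[0].label_source == LabelSource.NONE


@pytest.mark.parametrize(
    "content, message",
    [
        ("a\tB\nb\n", "mixed"),
        ("a\tQ\n", "label"),
        ("a\tB\tX\n", "fields"),
    ],
)
def test_read_conll_format_errors_name_the_line(tmp_path, content, message):
    path = tmp_path / "bad.conll"
    path.write_text(content)
    with pytest.raises(CorpusFormatError, match=message):
        read_conll(path)


def test_write_conll_single_sentence(tmp_path):
    corpus = Corpus([Sentence("c:0", ("x",), ("O",), LabelSource.GOLD)])
    path = tmp_path / "one.conll"
    write_conll(corpus, path)
    assert path.read_text() == "x\tO\n"


def test_write_conll_empty_corpus(tmp_path):
    path = tmp_path / "zero.conll"
    write_conll(Corpus([]), path)
    assert path.read_text() == ""


def test_write_conll_rejects_mixed_corpus(tmp_path):
    corpus = Corpus(
        [
            Sentence("c:0", ("x",), ("O",), LabelSource.GOLD),
            Sentence("c:1", ("y",)),
        ]
    )
    with pytest.raises(ValueError, match="mixes"):
        write_conll(corpus, tmp_path / "m.conll")


@settings(max_examples=30, deadline=None)
@given(st.data())
def test_conll_round_trip_is_byte_stable(tmp_path_factory, data):
    rng_sentences = data.draw(
        st.lists(
            st.lists(
                st.text(
                    alphabet=st.characters(
                        codec="ascii", exclude_characters="\t\n\r ", min_codepoint=33
                    ),
                    min_size=1,
                    max_size=6,
                ),
                min_size=1,
                max_size=6,
            ),
            min_size=0,
            max_size=5,
        )
    )
    labeled = data.draw(st.booleans())
    sentences = []
    for i, toks in enumerate(rng_sentences):
        if labeled:
            labels = tuple(
                data.draw(st.sampled_from(["B", "I", "O"])) for _ in toks
            )
            sentences.append(
                Sentence(f"g:{i}", tuple(toks), labels, LabelSource.GOLD)
            )
        else:
            sentences.append(Sentence(f"g:{i}", tuple(toks)))
    corpus = Corpus(sentences, name="g")
    tmp = tmp_path_factory.mktemp("conll")
    p1, p2 = tmp / "a.conll", tmp / "b.conll"
    write_conll(corpus, p1)
    back = read_conll(p1, name="g")
    assert [s.tokens for s in back] == [s.tokens for s in corpus]
    assert [s.labels for s in back] == [s.labels for s in corpus]
    write_conll(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


# -- BIO <-> spans -----------------------------------------------------------


@pytest.mark.parametrize(
    "labels, expected",
    [
        (["O", "O", "O"], []),
        (["B", "I", "O", "B"], [(0, 2), (3, 4)]),
        (["B"], [(0, 1)]),
        (["B", "B"], [(0, 1), (1, 2)]),
        (["B", "I", "I"], [(0, 3)]),
    ],
)
def test_parse_bio_examples(labels, expected):
    assert [(s.start, s.end) for s in parse_bio(labels)] == expected


def test_parse_bio_orphan_i_lenient_vs_strict():
    assert [(s.start, s.end) for s in parse_bio(["O", "I", "I"])] == [(1, 3)]
    with pytest.raises(CorpusFormatError, match="index 1"):
        parse_bio(["O", "I", "I"], strict=True)
    assert [(s.start, s.end) for s in parse_bio(["I", "O"])] == [(0, 1)]


@pytest.mark.parametrize(
    "spans, n, expected",
    [
        ([], 3, ["O", "O", "O"]),
        ([(0, 2), (3, 4)], 4, ["B", "I", "O", "B"]),
        ([(0, 1), (1, 2)], 2, ["B", "B"]),
    ],
)
def test_spans_to_bio_examples(spans, n, expected):
    assert spans_to_bio([EntitySpan(*s) for s in spans], n) == expected


def test_spans_to_bio_rejects_overlap_and_out_of_bounds():
    with pytest.raises(ValueError, match="overlap"):
        spans_to_bio([EntitySpan(0, 2), EntitySpan(1, 3)], 4)
    with pytest.raises(ValueError, match="exceeds"):
        spans_to_bio([EntitySpan(0, 5)], 3)


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(1, 12))
def test_bio_span_round_trip(seed, n):
    import numpy as np

    labels = random_bio(np.random.default_rng(seed), n)
    spans = parse_bio(labels, strict=True)
    assert spans_to_bio(spans, n) == labels
    # spans sorted, disjoint, in bounds
    for a, b in zip(spans, spans[1:]):
        assert a.end <= b.start
    assert all(0 <= s.start < s.end <= n for s in spans)
    assert parse_bio(spans_to_bio(spans, n)) == spans


# -- splitting ---------------------------------------------------------------


def _make_corpus(n):
    return Corpus([Sentence(f"c:{i}", ("w",)) for i in range(n)], name="c")


def test_split_sizes_exact_fractions():
    parts = split_corpus(_make_corpus(10), SplitSpec((0.8, 0.2), seed=0))
    assert [len(p) for p in parts] == [8, 2]


def test_split_identity_single_fraction():
    corpus = _make_corpus(7)
    (part,) = split_corpus(corpus, SplitSpec((1.0,), seed=3))
    assert part.ids == corpus.ids


def test_split_largest_remainder_rounding():
    # 7 * (0.8, 0.2) = (5.6, 1.4): remainder goes to the first fraction
    parts = split_corpus(_make_corpus(7), SplitSpec((0.8, 0.2), seed=0))
    assert [len(p) for p in parts] == [6, 1]


def test_split_determinism_and_seed_sensitivity():
    corpus = _make_corpus(40)
    a1 = split_corpus(corpus, SplitSpec((0.8, 0.2), seed=5))
    a2 = split_corpus(corpus, SplitSpec((0.8, 0.2), seed=5))
    b = split_corpus(corpus, SplitSpec((0.8, 0.2), seed=6))
    assert [p.ids for p in a1] == [p.ids for p in a2]
    assert [len(p) for p in a1] == [len(p) for p in b]
    assert a1[0].ids != b[0].ids  # overwhelmingly likely for 40 sentences


@settings(max_examples=25, deadline=None)
@given(st.integers(1, 50), st.integers(0, 2**31 - 1))
def test_split_parts_partition_the_corpus(n, seed):
    corpus = _make_corpus(n)
    parts = split_corpus(corpus, SplitSpec((0.5, 0.3, 0.2), seed=seed))
    ids = [i for p in parts for i in p.ids]
    assert sorted(ids) == sorted(corpus.ids)
    assert len(set(ids)) == n
    assert sum(len(p) for p in parts) == n


def test_split_rejects_bad_fractions():
    with pytest.raises(ValueError):
        SplitSpec((0.5, 0.4), seed=0)
    with pytest.raises(ValueError):
        SplitSpec((0.5, -0.5, 1.0), seed=0)
    with pytest.raises(ValueError):
        split_corpus(Corpus([]), SplitSpec((0.8, 0.2), seed=0))


def test_entity_word_fraction():
    corpus = Corpus(
        [
            Sentence("c:0", ("a", "b", "c", "d"), ("B", "I", "O", "O"), LabelSource.GOLD),
            Sentence("c:1", ("e", "f"), ("O", "B"), LabelSource.GOLD),
        ]
    )
    assert math.isclose(corpus.entity_word_fraction(), 3 / 6)
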
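"""Entity-level exact/partial scoring and Correct/Partial/Missing/Spurious
accounting, including an independent set-based cross-check of exact F1."""

import numpy as np
import pytest

from bionerst import (
    Corpus,
    EntitySpan,
    LabelSource,
    MatchCounts,
    Sentence,
    compute_metrics,
    evaluate_corpus,
    match_entities,
    parse_bio,
)

from conftest import random_bio


def spans(*pairs):
    return [EntitySpan(a, b) for a, b in pairs]


# -- matching ----------------------------------------------------------------


@pytest.mark.parametrize(
    "gold, pred, expected",
    [
        # one exact match, one overlap
        ([(0, 2), (5, 6)], [(0, 2), (5, 7)], (1, 1, 0, 0)),
        ([], [], (0, 0, 0, 0)),
        # disjoint spans: one missing, one spurious
        ([(0, 3)], [(4, 5)], (0, 0, 1, 1)),
        # pure overlap
        ([(1, 4)], [(2, 6)], (0, 1, 0, 0)),
        # one predicted span can serve at most one gold span
        ([(0, 2), (2, 4)], [(1, 3)], (0, 1, 1, 0)),
        # prediction matches nothing, gold matched exactly
        ([(0, 1)], [(0, 1), (3, 5)], (1, 0, 0, 1)),
    ],
)
def test_match_entities_cases(gold, pred, expected):
    counts = match_entities(spans(*gold), spans(*pred))
    assert (
        counts.correct,
        counts.partial,
        counts.missing,
        counts.spurious,
    ) == expected
    assert counts.incorrect == 0
    assert counts.possible == len(gold)
    assert counts.actual == len(pred)


def test_match_entities_prefers_largest_overlap():
    # gold (0,4) overlaps pred (0,1) by 1 and pred (1,4) by 3: the larger
    # overlap pairs first, leaving (0,1) spurious
    counts = match_entities(spans((0, 4), (5, 6)), spans((0, 1), (1, 4)))
    assert counts.partial == 1
    assert counts.missing == 1  # (5,6) unmatched
    assert counts.spurious == 1


def test_match_entities_rejects_overlapping_input():
    with pytest.raises(ValueError, match="overlapping"):
        match_entities(spans((0, 2), (1, 3)), [])
    with pytest.raises(ValueError, match="overlapping"):
        match_entities([], spans((0, 2), (1, 3)))


# -- metric derivation -------------------------------------------------------

HAND_CASES = [
    # (counts, exact P, exact R, exact F1, partial P, partial R, partial F1)
    (MatchCounts(1, 0, 1, 0, 0), 0.5, 0.5, 0.5, 0.75, 0.75, 0.75),
    (MatchCounts(0, 0, 0, 0, 0), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    (MatchCounts(2, 0, 0, 0, 0), 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    (MatchCounts(0, 0, 0, 3, 0), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    (MatchCounts(0, 0, 0, 0, 4), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    (MatchCounts(3, 0, 0, 1, 0), 1.0, 0.75, 6 / 7, 1.0, 0.75, 6 / 7),
    (MatchCounts(3, 0, 0, 0, 1), 0.75, 1.0, 6 / 7, 0.75, 1.0, 6 / 7),
    (MatchCounts(0, 0, 2, 0, 0), 0.0, 0.0, 0.0, 0.5, 0.5, 0.5),
    (MatchCounts(1, 0, 1, 1, 1), 1 / 3, 1 / 3, 1 / 3, 0.5, 0.5, 0.5),
    (MatchCounts(2, 0, 1, 1, 2), 0.4, 0.5, 4 / 9, 0.5, 0.625, 5 / 9),
    (MatchCounts(5, 0, 3, 2, 0), 0.625, 0.5, 5 / 9, 0.8125, 0.65, 0.7222222222222222),
]


@pytest.mark.parametrize("counts, ep, er, ef, pp, pr, pf", HAND_CASES)
def test_compute_metrics_hand_cases(counts, ep, er, ef, pp, pr, pf):
    report = compute_metrics(counts)
    assert report.exact_precision == pytest.approx(ep, abs=1e-12)
    assert report.exact_recall == pytest.approx(er, abs=1e-12)
    assert report.exact_f1 == pytest.approx(ef, abs=1e-12)
    assert report.partial_precision == pytest.approx(pp, abs=1e-12)
    assert report.partial_recall == pytest.approx(pr, abs=1e-12)
    assert report.partial_f1 == pytest.approx(pf, abs=1e-12)


def test_match_counts_rejects_negative():
    with pytest.raises(ValueError):
        MatchCounts(correct=-1)


# -- corpus-level aggregation ------------------------------------------------


def _gold_corpus():
    return Corpus(
        [
            Sentence(
                "g:0",
                tuple("abcdefg"),
                ("B", "I", "O", "O", "O", "B", "O"),
                LabelSource.GOLD,
            ),
            Sentence("g:1", tuple("hij"), ("B", "I", "I"), LabelSource.GOLD),
        ],
        name="g",
    )


def test_evaluate_corpus_perfect_predictions():
    corpus = _gold_corpus()
    report = evaluate_corpus(corpus, [s.labels for s in corpus])
    assert report.exact_f1 == 1.0
    assert report.partial_f1 == 1.0
    assert report.counts.correct == 3


def test_evaluate_corpus_all_O_predictions():
    corpus = _gold_corpus()
    report = evaluate_corpus(corpus, [("O",) * len(s) for s in corpus])
    assert report.counts.missing == 3
    assert report.counts.actual == 0
    assert report.exact_f1 == 0.0 and report.partial_f1 == 0.0


def test_evaluate_corpus_micro_additivity():
    # sentence 0: exact (0,2) + overlap on (5,6)->(5,7); sentence 1: miss + spurious
    corpus = Corpus(
        [
            Sentence(
                "g:0",
                tuple("abcdefg"),
                ("B", "I", "O", "O", "O", "B", "O"),
                LabelSource.GOLD,
            ),
            Sentence("g:1", tuple("hijkl"), ("B", "I", "I", "O", "O"), LabelSource.GOLD),
        ],
        name="g",
    )
    preds = [
        ("B", "I", "O", "O", "O", "B", "I"),
        ("O", "O", "O", "O", "B"),
    ]
    report = evaluate_corpus(corpus, preds)
    c = report.counts
    assert (c.correct, c.partial, c.missing, c.spurious) == (1, 1, 1, 1)
    assert report.exact_f1 == pytest.approx(
        compute_metrics(MatchCounts(1, 0, 1, 1, 1)).exact_f1
    )


def test_evaluate_corpus_permutation_invariance():
    corpus = _gold_corpus()
    preds = {"g:0": ("B", "I", "O", "O", "O", "O", "O"), "g:1": ("B", "I", "O")}
    swapped = Corpus(list(corpus)[::-1], name="g")
    r1 = evaluate_corpus(corpus, preds)
    r2 = evaluate_corpus(swapped, preds)
    assert r1 == r2


def test_evaluate_corpus_errors_name_the_sentence():
    corpus = _gold_corpus()
    with pytest.raises(ValueError, match="g:1"):
        evaluate_corpus(corpus, {"g:0": ("O",) * 7})
    with pytest.raises(ValueError, match="g:0"):
        evaluate_corpus(corpus, {"g:0": ("O",), "g:1": ("O", "O", "O")})


# -- randomized invariants and independent cross-check -----------------------


def independent_exact_f1(gold_labels, pred_labels):
    """Set-intersection exact-match F1, written without the matching code."""
    gold = {
        (i, s.start, s.end)
        for i, labs in enumerate(gold_labels)
        for s in parse_bio(labs)
    }
    pred = {
        (i, s.start, s.end)
        for i, labs in enumerate(pred_labels)
        for s in parse_bio(labs)
    }
    tp = len(gold & pred)
    p = tp / len(pred) if pred else 0.0
    r = tp / len(gold) if gold else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def test_random_bio_pairs_conservation_and_partial_dominance():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(1, 15))
        gold = random_bio(rng, n)
        pred = random_bio(rng, n)
        counts = match_entities(parse_bio(gold), parse_bio(pred))
        assert counts.correct + counts.partial + counts.missing == len(parse_bio(gold))
        assert counts.correct + counts.partial + counts.spurious == len(parse_bio(pred))
        report = compute_metrics(counts)
        assert report.partial_f1 >= report.exact_f1 - 1e-12
        assert report.partial_precision >= report.exact_precision - 1e-12
        assert report.partial_recall >= report.exact_recall - 1e-12


def test_exact_f1_agrees_with_independent_span_set_scorer():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n_sent = int(rng.integers(1, 5))
        gold_labels, pred_labels, sentences = [], [], []
        for i in range(n_sent):
            n = int(rng.integers(1, 12))
            g = random_bio(rng, n)
            gold_labels.append(g)
            pred_labels.append(random_bio(rng, n))
            sentences.append(
                Sentence(f"r:{i}", ("w",) * n, tuple(g), LabelSource.GOLD)
            )
        report = evaluate_corpus(Corpus(sentences, name="r"), pred_labels)
        assert report.exact_f1 == pytest.approx(
            independent_exact_f1(gold_labels, pred_labels), abs=1e-12
        )
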
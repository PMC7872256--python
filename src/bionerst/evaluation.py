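"""Entity-level exact and partial precision/recall/F1 (SemEval 2013 task 9.1
style), with Correct / Incorrect / Partial / Missing / Spurious accounting.

Entities are untyped spans, so the Incorrect category (wrong entity type) is
structurally zero here.  Definitions:

    possible = correct + incorrect + partial + missing   (gold entities)
    actual   = correct + incorrect + partial + spurious  (predicted entities)

    exact precision   = correct / actual
    exact recall      = correct / possible
    partial precision = (correct + 0.5 * partial) / actual
    partial recall    = (correct + 0.5 * partial) / possible

with F1 the harmonic mean of its precision and recall, and every 0/0 ratio
defined as 0.  Matching is one-to-one: identical spans pair first (Correct);
remaining overlapping gold/predicted pairs are then matched greedily,
largest overlap first with positional tie-breaks (Partial); leftovers are
Missing (gold) or Spurious (predicted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus import Corpus, EntitySpan, parse_bio


@dataclass(frozen=True)
class MatchCounts:
    correct: int = 0
    incorrect: int = 0
    partial: int = 0
    missing: int = 0
    spurious: int = 0

    def __post_init__(self) -> None:
        for f in ("correct", "incorrect", "partial", "missing", "spurious"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def possible(self) -> int:
        return self.correct + self.incorrect + self.partial + self.missing

    @property
    def actual(self) -> int:
        return self.correct + self.incorrect + self.partial + self.spurious

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.correct + other.correct,
            self.incorrect + other.incorrect,
            self.partial + other.partial,
            self.missing + other.missing,
            self.spurious + other.spurious,
        )


@dataclass(frozen=True)
class MetricReport:
    exact_precision: float
    exact_recall: float
    exact_f1: float
    partial_precision: float
    partial_recall: float
    partial_f1: float
    counts: MatchCounts

    def as_dict(self) -> dict[str, float | int]:
        d: dict[str, float | int] = {
            "exact_precision": self.exact_precision,
            "exact_recall": self.exact_recall,
            "exact_f1": self.exact_f1,
            "partial_precision": self.partial_precision,
            "partial_recall": self.partial_recall,
            "partial_f1": self.partial_f1,
        }
        for f in ("correct", "incorrect", "partial", "missing", "spurious"):
            d[f] = getattr(self.counts, f)
        return d


def _validate_disjoint(spans: Sequence[EntitySpan], which: str) -> list[EntitySpan]:
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.end > b.start:
            raise ValueError(f"overlapping spans within {which} list: {a}, {b}")
    return ordered


def match_entities(
    gold_spans: Sequence[EntitySpan], pred_spans: Sequence[EntitySpan]
) -> MatchCounts:
    """One-to-one matching of gold vs. predicted spans of one sentence."""
    gold = _validate_disjoint(gold_spans, "gold")
    pred = _validate_disjoint(pred_spans, "predicted")

    gold_free = set(range(len(gold)))
    pred_free = set(range(len(pred)))
    pred_index = {span: i for i, span in enumerate(pred)}

    correct = 0
    for gi, g in enumerate(gold):
        pi = pred_index.get(g)
        if pi is not None and pi in pred_free:
            correct += 1
            gold_free.discard(gi)
            pred_free.discard(pi)

    # greedy partial matching: largest overlap first, ties toward the
    # earlier gold span, then the earlier predicted span
    candidates = [
        (g.overlap(p), gi, pi)
        for gi in sorted(gold_free)
        for pi in sorted(pred_free)
        for g, p in ((gold[gi], pred[pi]),)
        if g.overlap(p) > 0
    ]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    partial = 0
    for _, gi, pi in candidates:
        if gi in gold_free and pi in pred_free:
            partial += 1
            gold_free.discard(gi)
            pred_free.discard(pi)

    counts = MatchCounts(
        correct=correct,
        incorrect=0,
        partial=partial,
        missing=len(gold_free),
        spurious=len(pred_free),
    )
    assert counts.possible == len(gold) and counts.actual == len(pred)
    return counts


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) else 0.0


def compute_metrics(counts: MatchCounts) -> MetricReport:
    """Derive the six exact/partial metrics from match counts."""
    exact_p = _ratio(counts.correct, counts.actual)
    exact_r = _ratio(counts.correct, counts.possible)
    partial_credit = counts.correct + 0.5 * counts.partial
    partial_p = _ratio(partial_credit, counts.actual)
    partial_r = _ratio(partial_credit, counts.possible)
    return MetricReport(
        exact_precision=exact_p,
        exact_recall=exact_r,
        exact_f1=_f1(exact_p, exact_r),
        partial_precision=partial_p,
        partial_recall=partial_r,
        partial_f1=_f1(partial_p, partial_r),
        counts=counts,
    )


def evaluate_corpus(
    gold_corpus: Corpus,
    predictions: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
) -> MetricReport:
    """Micro-aggregated report over a corpus.

    ``predictions`` is either a mapping from sentence id to a BIO sequence
    or a list aligned with corpus order.  Counts are summed over sentences
    and the metrics computed once from the totals.
    """
    if not isinstance(predictions, Mapping):
        if len(predictions) != len(gold_corpus):
            raise ValueError(
                f"{len(predictions)} predictions for {len(gold_corpus)} sentences"
            )
        predictions = dict(zip(gold_corpus.ids, predictions))
    total = MatchCounts()
    for sent in gold_corpus:
        if sent.labels is None:
            raise ValueError(f"gold sentence {sent.id!r} is unlabeled")
        if sent.id not in predictions:
            raise ValueError(f"no prediction for sentence {sent.id!r}")
        pred_labels = predictions[sent.id]
        if len(pred_labels) != len(sent):
            raise ValueError(
                f"sentence {sent.id!r}: prediction length {len(pred_labels)} "
                f"!= sentence length {len(sent)}"
            )
        total = total + match_entities(sent.spans(), parse_bio(pred_labels))
    return compute_metrics(total)
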
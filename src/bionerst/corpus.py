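"""BIO-annotated corpora: data model, CoNLL-style I/O, span conversion, splitting.

A corpus is an ordered collection of pre-tokenized sentences.  Each sentence
optionally carries one BIO tag per token (B = entity-initial, I = entity
continuation, O = outside).  Entities are represented as 0-based half-open
token intervals, which are closed under concatenation and make off-by-one
errors loud.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

BIO_LABELS = ("B", "I", "O")


class CorpusFormatError(ValueError):
    """Raised for malformed CoNLL input or invalid BIO sequences."""


class LabelSource(str, Enum):
    GOLD = "gold"
    PSEUDO = "pseudo"
    NONE = "none"


@dataclass(frozen=True)
class EntitySpan:
    """Half-open token interval [start, end) of one named entity."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def overlap(self, other: "EntitySpan") -> int:
        """Number of tokens shared with ``other``."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Sentence:
    id: str
    tokens: tuple[str, ...]
    labels: tuple[str, ...] | None = None
    label_source: LabelSource = LabelSource.NONE

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError(f"sentence {self.id!r} has no tokens")
        if self.labels is not None:
            if len(self.labels) != len(self.tokens):
                raise ValueError(
                    f"sentence {self.id!r}: {len(self.labels)} labels for "
                    f"{len(self.tokens)} tokens"
                )
            bad = [l for l in self.labels if l not in BIO_LABELS]
            if bad:
                raise ValueError(f"sentence {self.id!r}: non-BIO label {bad[0]!r}")
        if self.labels is None and self.label_source != LabelSource.NONE:
            raise ValueError(f"sentence {self.id!r}: label_source set without labels")

    def __len__(self) -> int:
        return len(self.tokens)

    def with_labels(
        self, labels: Sequence[str], source: LabelSource
    ) -> "Sentence":
        return replace(self, labels=tuple(labels), label_source=source)

    def without_labels(self) -> "Sentence":
        return replace(self, labels=None, label_source=LabelSource.NONE)

    def spans(self, strict: bool = False) -> list[EntitySpan]:
        if self.labels is None:
            raise ValueError(f"sentence {self.id!r} is unlabeled")
        return parse_bio(self.labels, strict=strict)


@dataclass
class Corpus:
    sentences: list[Sentence] = field(default_factory=list)
    name: str = "corpus"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sentences]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sentence id {dup!r} in corpus {self.name!r}")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    def __getitem__(self, i: int) -> Sentence:
        return self.sentences[i]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sentences]

    def is_labeled(self) -> bool:
        return all(s.labels is not None for s in self.sentences)

    def n_entities(self) -> int:
        return sum(len(s.spans()) for s in self.sentences)

    def entity_word_fraction(self) -> float:
        """Fraction of tokens inside gold entities, the density statistic
        used to characterise corpora (benchmarks span roughly .01-.41)."""
        ent = sum(sp.end - sp.start for s in self.sentences for sp in s.spans())
        tot = sum(len(s) for s in self.sentences)
        return ent / tot if tot else 0.0


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random partition of a corpus into len(fractions) parts."""

    fractions: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.fractions) < 1:
            raise ValueError("need at least one fraction")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions sum to {sum(self.fractions)}, not 1")


def parse_bio(labels: Sequence[str], strict: bool = False) -> list[EntitySpan]:
    """Decode a BIO sequence into entity spans.

    Lenient mode (default) promotes an orphan I (at position 0 or after O)
    to B, since model-predicted label sequences can be arbitrary.  Strict
    mode raises instead, for validating gold annotations.
    """
    spans: list[EntitySpan] = []
    start: int | None = None
    for i, lab in enumerate(labels):
        if lab not in BIO_LABELS:
            raise CorpusFormatError(f"non-BIO label {lab!r} at index {i}")
        if lab == "B":
            if start is not None:
                spans.append(EntitySpan(start, i))
            start = i
        elif lab == "I":
            if start is None:
                if strict:
                    raise CorpusFormatError(f"orphan I at index {i}")
                start = i
        else:
            if start is not None:
                spans.append(EntitySpan(start, i))
                start = None
    if start is not None:
        spans.append(EntitySpan(start, len(labels)))
    return spans


def spans_to_bio(spans: Iterable[EntitySpan], n: int) -> list[str]:
    """Encode non-overlapping spans as a BIO sequence of length ``n``.

    Adjacent spans yield B,B at the boundary; inverse of :func:`parse_bio`.
    """
    ordered = sorted(spans, key=lambda s: s.start)
    labels = ["O"] * n
    prev_end = 0
    for sp in ordered:
        if sp.start < prev_end:
            raise ValueError(f"overlapping spans at token {sp.start}")
        if sp.end > n:
            raise ValueError(f"span ({sp.start}, {sp.end}) exceeds length {n}")
        labels[sp.start] = "B"
        for j in range(sp.start + 1, sp.end):
            labels[j] = "I"
        prev_end = sp.end
    return labels


def read_conll(path: str | Path, name: str | None = None) -> Corpus:
    """Read a token-per-line file: ``token<TAB>label`` or bare ``token``
    lines, blank lines between sentences.  Sentence ids are assigned as
    ``<corpus>:<index>``.
    """
    path = Path(path)
    corpus_name = name if name is not None else path.stem
    sentences: list[Sentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    has_label: bool | None = None
    block_start = 1

    def flush(line_no: int) -> None:
        nonlocal tokens, labels, has_label, block_start
        if not tokens:
            return
        idx = len(sentences)
        if has_label:
            sent = Sentence(
                f"{corpus_name}:{idx}",
                tuple(tokens),
                tuple(labels),
                LabelSource.GOLD,
            )
        else:
            sent = Sentence(f"{corpus_name}:{idx}", tuple(tokens))
        sentences.append(sent)
        tokens, labels, has_label = [], [], None
        block_start = line_no + 1

    with open(path, encoding="utf-8") as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(line_no)
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                labeled = False
                tok, lab = parts[0], None
            elif len(parts) == 2:
                labeled = True
                tok, lab = parts
                if lab not in BIO_LABELS:
                    raise CorpusFormatError(
                        f"{path}:{line_no}: label {lab!r} not in {{B,I,O}}"
                    )
            else:
                raise CorpusFormatError(
                    f"{path}:{line_no}: expected 1 or 2 tab-separated fields"
                )
            if has_label is None:
                has_label = labeled
            elif has_label != labeled:
                raise CorpusFormatError(
                    f"{path}:{line_no}: mixed labeled/unlabeled lines in one sentence"
                )
            tokens.append(tok)
            if lab is not None:
                labels.append(lab)
        flush(line_no + 1)
    return Corpus(sentences, name=corpus_name)


def write_conll(corpus: Corpus, path: str | Path) -> None:
    """Write the dialect read by :func:`read_conll`; deterministic."""
    labeled = [s.labels is not None for s in corpus]
    if any(labeled) and not all(labeled):
        raise ValueError("corpus mixes labeled and unlabeled sentences")
    with open(path, "w", encoding="utf-8") as fh:
        for k, sent in enumerate(corpus):
            if k:
                fh.write("\n")
            if sent.labels is not None:
                for tok, lab in zip(sent.tokens, sent.labels):
                    fh.write(f"{tok}\t{lab}\n")
            else:
                for tok in sent.tokens:
                    fh.write(f"{tok}\n")


def split_corpus(corpus: Corpus, spec: SplitSpec) -> list[Corpus]:
    """Partition a corpus by a seeded uniform permutation.

    Part sizes are the fractions rounded by largest remainder (ties broken
    toward the earlier fraction), so e.g. 1000 sentences at 80/20 always
    gives exactly (800, 200).
    """
    n = len(corpus)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    exact = [f * n for f in spec.fractions]
    sizes = [int(math.floor(x)) for x in exact]
    remainder = n - sum(sizes)
    by_frac = sorted(
        range(len(exact)), key=lambda i: (-(exact[i] - sizes[i]), i)
    )
    for i in by_frac[:remainder]:
        sizes[i] += 1
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    parts: list[Corpus] = []
    offset = 0
    for k, size in enumerate(sizes):
        idx = sorted(order[offset : offset + size].tolist())
        parts.append(
            Corpus([corpus[i] for i in idx], name=f"{corpus.name}/part{k}")
        )
        offset += size
    return parts
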
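"""Seeded generator of source/target corpus pairs with planted entities.

The generator emulates the statistical skeleton of paired biomedical NER
corpora: a large silver-standard source corpus and a smaller gold target
corpus whose entity lexicons overlap by a controllable fraction (real
pre-training/benchmark pairs overlap by roughly 9%-68%), with entity-word
densities in the range seen across real corpora (about .01-.41 of all
tokens) and label noise standing in for rule-based annotation.

Background words are drawn Zipf-like from a background vocabulary; entity
mentions are 1-3 reserved entity-pool words inserted into distinct gaps so
that two entities are always separated by at least one background token.
Background and entity word pools are disjoint, which makes gold labels
unambiguous and the planted rule learnable — the generator's job is
testability, not linguistic realism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .corpus import Corpus, EntitySpan, LabelSource, Sentence, spans_to_bio

#: Entity-word densities mimicking the three corpus families used for
#: pre-training and benchmarking.
DENSITY_PRESETS = {
    "benchmark-like": 0.05,
    "semmed-like": 0.27,
    "medmentions-like": 0.41,
}

Lexicon = tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class SynthConfig:
    background_vocab_size: int = 500
    source_lexicon_size: int = 300
    target_lexicon_size: int = 100
    lexicon_overlap: float = 0.5
    entity_density: float = 0.05
    entity_length_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    boundary_noise_rate: float = 0.0
    omission_rate: float = 0.0
    sentence_length_range: tuple[int, int] = (6, 14)
    n_sentences: int = 1000
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lexicon_overlap <= 1.0):
            raise ValueError("lexicon_overlap must be in [0, 1]")
        if not (0.0 < self.entity_density < 1.0):
            raise ValueError("entity_density must be in (0, 1)")
        for r in (self.boundary_noise_rate, self.omission_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("noise rates must be in [0, 1]")
        lo, hi = self.sentence_length_range
        if lo < 2 or hi < lo:
            raise ValueError("sentence_length_range must be (lo, hi) with 2 <= lo <= hi")
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be non-negative")
        if abs(sum(self.entity_length_weights) - 1.0) > 1e-9:
            raise ValueError("entity_length_weights must sum to 1")
        self.check_density_feasible()

    @property
    def mean_entity_length(self) -> float:
        w = self.entity_length_weights
        return 1 * w[0] + 2 * w[1] + 3 * w[2]

    def check_density_feasible(self) -> None:
        """In expectation a sentence of length L holds d*L entity words in
        about d*L/ml entities, each needing a separating background token;
        require this to fit the shortest sentences."""
        lo = self.sentence_length_range[0]
        ml = self.mean_entity_length
        limit = (1.0 + 1.0 / lo) / (1.0 + 1.0 / ml)
        if self.entity_density > limit:
            raise ValueError(
                f"entity_density {self.entity_density} infeasible for length "
                f"range {self.sentence_length_range} (limit ~{limit:.3f})"
            )


def _role_seed(seed: int, role: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(role.encode())) % (2**31 - 1)


def _draw_unique_entities(
    rng: np.random.Generator,
    pool: list[str],
    count: int,
    weights: tuple[float, float, float],
    taken: set[tuple[str, ...]],
) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 100 * count + 1000:
            raise ValueError("entity-word pool too small for requested lexicon sizes")
        length = int(rng.choice((1, 2, 3), p=weights))
        ent = tuple(pool[i] for i in rng.choice(len(pool), size=length, replace=False))
        if ent not in taken:
            taken.add(ent)
            out.append(ent)
    return out


def make_lexicons(config: SynthConfig) -> tuple[Lexicon, Lexicon]:
    """Source and target entity lexicons sharing exactly
    round(overlap * target size) entries; deterministic by seed."""
    n_shared = round(config.lexicon_overlap * config.target_lexicon_size)
    if n_shared > config.source_lexicon_size:
        raise ValueError(
            f"overlap requires {n_shared} shared entities but source lexicon "
            f"holds only {config.source_lexicon_size}"
        )
    rng = np.random.default_rng(_role_seed(config.seed, "lexicons"))
    pool_size = max(
        100, 3 * (config.source_lexicon_size + config.target_lexicon_size)
    )
    pool = [f"ent{i}" for i in range(pool_size)]
    taken: set[tuple[str, ...]] = set()
    shared = _draw_unique_entities(
        rng, pool, n_shared, config.entity_length_weights, taken
    )
    target_only = _draw_unique_entities(
        rng,
        pool,
        config.target_lexicon_size - n_shared,
        config.entity_length_weights,
        taken,
    )
    source_only = _draw_unique_entities(
        rng,
        pool,
        config.source_lexicon_size - n_shared,
        config.entity_length_weights,
        taken,
    )
    return tuple(shared + source_only), tuple(shared + target_only)


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    p = 1.0 / np.arange(1, n + 1) ** exponent
    return p / p.sum()


def generate_corpus(lexicon: Lexicon, config: SynthConfig, role: str) -> Corpus:
    """Generate ``config.n_sentences`` gold-labeled sentences for ``role``
    (role names the corpus and salts its seed)."""
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(_role_seed(config.seed, role))
    probs = _zipf_probs(config.background_vocab_size, config.zipf_exponent)
    background = [f"w{i}" for i in range(config.background_vocab_size)]
    lo, hi = config.sentence_length_range
    ml = config.mean_entity_length
    sentences: list[Sentence] = []
    for idx in range(config.n_sentences):
        L = int(rng.integers(lo, hi + 1))
        k = int(rng.poisson(config.entity_density * L / ml))
        ents = [lexicon[i] for i in rng.integers(0, len(lexicon), size=k)]
        # trim until entity words + one separator between entities fit
        while ents and sum(map(len, ents)) + (len(ents) - 1) > L:
            ents.pop()
        k = len(ents)
        n_bg = L - sum(map(len, ents))
        bg_idx = rng.choice(config.background_vocab_size, size=n_bg, p=probs)
        bg = [background[i] for i in bg_idx]
        gaps = sorted(rng.choice(n_bg + 1, size=k, replace=False)) if k else []
        tokens: list[str] = []
        spans: list[EntitySpan] = []
        gi = 0
        for g, ent in zip(gaps, ents):
            tokens.extend(bg[gi:g])
            gi = g
            spans.append(EntitySpan(len(tokens), len(tokens) + len(ent)))
            tokens.extend(ent)
        tokens.extend(bg[gi:])
        labels = spans_to_bio(spans, len(tokens))
        sentences.append(
            Sentence(f"{role}:{idx}", tuple(tokens), tuple(labels), LabelSource.GOLD)
        )
    return Corpus(sentences, name=role)


def corrupt_labels(corpus: Corpus, config: SynthConfig) -> Corpus:
    """Silver-standard corruption: per entity, omit its labels entirely with
    ``omission_rate``, otherwise shift one boundary by one token with
    ``boundary_noise_rate`` (clipped to the sentence, never overlapping a
    neighboring span).  Tokens are untouched; deterministic by seed."""
    rng = np.random.default_rng(_role_seed(config.seed, f"corrupt:{corpus.name}"))
    out: list[Sentence] = []
    for sent in corpus:
        spans = sent.spans(strict=True)
        kept: list[EntitySpan] = []
        for j, sp in enumerate(spans):
            if rng.random() < config.omission_rate:
                continue
            if rng.random() < config.boundary_noise_rate:
                # the previous span may itself have shifted; compare against
                # its corrupted position so spans never collide
                prev_end = kept[-1].end if kept else 0
                next_start = spans[j + 1].start if j + 1 < len(spans) else len(sent)
                moves = []
                if sp.start - 1 >= prev_end:
                    moves.append((sp.start - 1, sp.end))
                if sp.start + 1 < sp.end:
                    moves.append((sp.start + 1, sp.end))
                if sp.end - 1 > sp.start:
                    moves.append((sp.start, sp.end - 1))
                if sp.end + 1 <= next_start:
                    moves.append((sp.start, sp.end + 1))
                if moves:
                    sp = EntitySpan(*moves[int(rng.integers(len(moves)))])
            kept.append(sp)
        labels = spans_to_bio(kept, len(sent))
        out.append(sent.with_labels(labels, LabelSource.GOLD))
    return Corpus(out, name=corpus.name)


def entity_strings(corpus: Corpus) -> set[str]:
    """Case-folded, space-joined surface strings of all gold entity spans."""
    strings: set[str] = set()
    for sent in corpus:
        for sp in sent.spans():
            strings.add(" ".join(sent.tokens[sp.start : sp.end]).casefold())
    return strings


def overlap_statistic(source_corpus: Corpus, target_corpus: Corpus) -> float:
    """Fraction of unique target entity strings that also occur as labeled
    entities in the source corpus (the lexical-overlap dial of paired
    corpora)."""
    target = entity_strings(target_corpus)
    if not target:
        raise ValueError("target corpus has no labeled entities")
    source = entity_strings(source_corpus)
    return len(target & source) / len(target)


@dataclass(frozen=True)
class StudyData:
    """Fixed source/target conditions for one synthetic experiment."""

    source: Corpus
    target_pool: Corpus
    test: Corpus
    config: SynthConfig


def make_study_data(
    seed: int,
    n_source: int = 2000,
    n_target: int = 2000,
    n_test: int = 400,
    source_density: float = DENSITY_PRESETS["semmed-like"],
    target_density: float = 0.12,
    source_boundary_noise: float = 0.05,
    source_omission: float = 0.10,
    **overrides,
) -> StudyData:
    """Generate the canonical synthetic study: a silver-annotated source
    corpus (dense, noisy labels), a gold target pool to subsample labeled
    sets from, and a held-out gold test set sharing the target lexicon."""
    base = SynthConfig(seed=seed, **overrides)
    source_lex, target_lex = make_lexicons(base)
    src_cfg = replace(
        base,
        entity_density=source_density,
        n_sentences=n_source,
        boundary_noise_rate=source_boundary_noise,
        omission_rate=source_omission,
    )
    source = corrupt_labels(generate_corpus(source_lex, src_cfg, "source"), src_cfg)
    tgt_cfg = replace(base, entity_density=target_density, n_sentences=n_target)
    target_pool = generate_corpus(target_lex, tgt_cfg, "target")
    test_cfg = replace(base, entity_density=target_density, n_sentences=n_test)
    test = generate_corpus(target_lex, test_cfg, "test")
    return StudyData(source=source, target_pool=target_pool, test=test, config=base)
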
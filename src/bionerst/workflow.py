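"""Three-stage training workflow: pre-train on a large annotated source
corpus, fine-tune on a small labeled target set, then iteratively self-train
on unlabeled target sentences.

Self-training loop: train a model (re-initialized every iteration from the
pre-trained weights, or from the same fresh seeded initialization when no
pre-training is used), predict on the unsupervised set, and move every
sentence whose per-word confidence meets the threshold (default 99.75%)
into the training set with its predicted labels as pseudo-labels.  The
gold validation split is fixed once and never receives pseudo-labels.  The
loop ends when an iteration moves nothing, the unsupervised set empties, or
a safety cap is reached; the model trained on the final training set is
returned together with the per-iteration history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .corpus import Corpus, LabelSource, Sentence, SplitSpec, split_corpus
from .evaluation import MetricReport, evaluate_corpus
from .synthetic import StudyData
from .tagger import CrfTagger, EpochRecord, TaggerConfig, Vocabulary, fit

PRETRAIN_PATIENCE = 5
FINETUNE_PATIENCE = 10
DEFAULT_CONFIDENCE_THRESHOLD = 0.9975
TRAIN_VAL_SPLIT = (0.8, 0.2)


@dataclass(frozen=True)
class SelfTrainConfig:
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    max_iterations: int = 30
    refreeze_pseudo_labels: bool = True  # pseudo-labels frozen once moved

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    n_moved: int
    cumulative_pseudo_fraction: float
    val_report: MetricReport
    test_report: MetricReport | None = None


@dataclass
class FitResult:
    tagger: CrfTagger
    train: Corpus
    val: Corpus
    history: list[EpochRecord]


def pretrain(
    config: TaggerConfig,
    source_corpus: Corpus,
    seed: int,
    vocabulary: Vocabulary | None = None,
    embeddings: np.ndarray | None = None,
) -> FitResult:
    """Pre-train on a seeded 80/20 split of the source corpus with early
    stopping at patience 5 on validation exact-F1."""
    if len(source_corpus) < 5:
        raise ValueError("source corpus must hold at least 5 sentences")
    cfg = replace(config, patience=PRETRAIN_PATIENCE, seed=seed)
    train, val = split_corpus(source_corpus, SplitSpec(TRAIN_VAL_SPLIT, seed))
    tagger, history = fit(
        cfg, train, val, vocabulary=vocabulary, embeddings=embeddings
    )
    return FitResult(tagger, train, val, history)


def finetune(
    pretrained: CrfTagger | None,
    labeled_target: Corpus,
    seed: int,
    config: TaggerConfig,
    vocabulary: Vocabulary | None = None,
) -> FitResult:
    """Fine-tune on a seeded 80/20 split of the labeled target set with
    patience 10, initializing from pre-trained weights when given and from
    a fresh seeded initialization otherwise."""
    if len(labeled_target) < 5:
        raise ValueError("need at least 5 labeled sentences to fine-tune")
    cfg = replace(config, patience=FINETUNE_PATIENCE, seed=seed)
    train, val = split_corpus(labeled_target, SplitSpec(TRAIN_VAL_SPLIT, seed))
    if pretrained is not None:
        vocab = pretrained.vocab
        init = pretrained.get_weights()
    else:
        vocab = vocabulary
        init = None
    tagger, history = fit(cfg, train, val, vocabulary=vocab, init_weights=init)
    return FitResult(tagger, train, val, history)


def self_train(
    pretrained: CrfTagger | None,
    labeled_target: Corpus,
    unsup_set: Corpus,
    st_config: SelfTrainConfig,
    seed: int,
    config: TaggerConfig,
    vocabulary: Vocabulary | None = None,
    test: Corpus | None = None,
    inspect: "Callable[[int, list[Sentence], list[Sentence]], None] | None" = None,
) -> tuple[CrfTagger, list[IterationRecord]]:
    """Iterative confidence-thresholded self-training.

    Iteration k trains with seed ``seed + k - 1`` (k starting at 1), so the
    first iteration is bit-identical to :func:`finetune` with the same
    inputs; in particular a threshold no prediction reaches reduces the
    whole loop to plain fine-tuning.
    """
    if len(labeled_target) < 5:
        raise ValueError("need at least 5 labeled sentences to self-train")
    train_gold, val = split_corpus(labeled_target, SplitSpec(TRAIN_VAL_SPLIT, seed))
    if pretrained is not None:
        vocab = pretrained.vocab
        init = pretrained.get_weights()
    else:
        vocab = vocabulary or Vocabulary.build(labeled_target, unsup_set)
        init = None

    train_sents: list[Sentence] = list(train_gold)
    unsup: list[Sentence] = [s.without_labels() for s in unsup_set]
    total_available = len(labeled_target) + len(unsup)
    records: list[IterationRecord] = []
    cum_moved = 0
    iteration = 0
    while True:
        iteration += 1
        cfg = replace(
            config, patience=FINETUNE_PATIENCE, seed=seed + iteration - 1
        )
        tagger, _ = fit(
            cfg,
            Corpus(train_sents, name=f"{labeled_target.name}/selftrain"),
            val,
            vocabulary=vocab,
            init_weights=init,
        )
        val_report = _report(tagger, val)
        test_report = _report(tagger, test) if test is not None else None

        if not unsup or iteration > st_config.max_iterations:
            records.append(
                IterationRecord(
                    iteration, 0, cum_moved / total_available, val_report, test_report
                )
            )
            return tagger, records

        preds = tagger.predict(unsup)
        moved = [
            sent.with_labels(pred.labels, LabelSource.PSEUDO)
            for sent, pred in zip(unsup, preds)
            if pred.confidence >= st_config.confidence_threshold
        ]
        moved_ids = {s.id for s in moved}
        cum_moved += len(moved)
        records.append(
            IterationRecord(
                iteration,
                len(moved),
                cum_moved / total_available,
                val_report,
                test_report,
            )
        )
        if not moved:
            return tagger, records
        if not st_config.refreeze_pseudo_labels:
            # ablation: refresh the labels of previously moved sentences
            # with the current model (membership stays one-way)
            pseudo_idx = [
                i for i, s in enumerate(train_sents)
                if s.label_source == LabelSource.PSEUDO
            ]
            if pseudo_idx:
                repreds = tagger.predict([train_sents[i] for i in pseudo_idx])
                for i, pred in zip(pseudo_idx, repreds):
                    train_sents[i] = train_sents[i].with_labels(
                        pred.labels, LabelSource.PSEUDO
                    )
        train_sents.extend(moved)
        unsup = [s for s in unsup if s.id not in moved_ids]
        if inspect is not None:
            inspect(iteration, list(train_sents), list(unsup))


def _report(tagger: CrfTagger, corpus: Corpus) -> MetricReport:
    preds = tagger.predict(corpus.sentences)
    return evaluate_corpus(corpus, [p.labels for p in preds])


@dataclass(frozen=True)
class ScenarioConfig:
    """Grid of desk-scale experiments over labeled-set sizes and seeds.

    ``use_pretrain`` / ``use_selftrain``: True or False runs only that arm,
    None runs both arms of the factor.  Multiple ``thresholds`` turn the
    self-training arm into a confidence-threshold sweep.
    """

    labeled_sizes: tuple[int, ...] = (250, 500, 1000, 2000)
    seeds: tuple[int, ...] = (0,)
    use_pretrain: bool | None = None
    use_selftrain: bool | None = None
    include_fully_supervised: bool = False
    thresholds: tuple[float, ...] = (DEFAULT_CONFIDENCE_THRESHOLD,)
    tagger: TaggerConfig = field(default_factory=TaggerConfig.desk_scale)
    max_iterations: int = 30
    max_unsup: int | None = None  # cap on the unsupervised set (scaled-down runs)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.labeled_sizes):
            raise ValueError("labeled sizes must be positive")


@dataclass
class ScenarioResults:
    table: pd.DataFrame
    histories: dict[tuple, list[IterationRecord]]


def subsample_labeled(
    target_pool: Corpus, size: int, seed: int
) -> tuple[Corpus, Corpus]:
    """Split the target pool into a labeled subset of ``size`` sentences
    (seeded permutation; nested across sizes for one seed) and the
    remaining unsupervised set with labels stripped."""
    if size > len(target_pool):
        raise ValueError(
            f"labeled size {size} exceeds target pool of {len(target_pool)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(target_pool))
    lab_idx = sorted(order[:size].tolist())
    uns_idx = sorted(order[size:].tolist())
    labeled = Corpus([target_pool[i] for i in lab_idx], name=f"{target_pool.name}/labeled")
    unsup = Corpus(
        [target_pool[i].without_labels() for i in uns_idx],
        name=f"{target_pool.name}/unsup",
    )
    return labeled, unsup


def run_scenario(
    scenario: ScenarioConfig,
    data: StudyData,
    pretrained_cache: dict[int, CrfTagger] | None = None,
) -> ScenarioResults:
    """Run every (size, seed, arm) cell of the grid and evaluate on the
    held-out test corpus; returns a long-format table plus self-training
    iteration histories keyed by (size, seed, pretrain, threshold).

    ``pretrained_cache`` maps seed to an already pre-trained tagger so that
    several scenario grids over the same study data can share the (costly)
    pre-training stage; missing seeds are pre-trained on demand.
    """
    vocab = Vocabulary.build(data.source, data.target_pool, data.test)
    pre_arms = (
        (True, False) if scenario.use_pretrain is None else (scenario.use_pretrain,)
    )
    st_arms = (
        (True, False) if scenario.use_selftrain is None else (scenario.use_selftrain,)
    )
    rows: list[dict] = []
    histories: dict[tuple, list[IterationRecord]] = {}

    for seed in scenario.seeds:
        pretrained: CrfTagger | None = None
        if True in pre_arms:
            if pretrained_cache is not None and seed in pretrained_cache:
                pretrained = pretrained_cache[seed]
            else:
                pretrained = pretrain(
                    scenario.tagger, data.source, seed, vocabulary=vocab
                ).tagger
                if pretrained_cache is not None:
                    pretrained_cache[seed] = pretrained
        for size in scenario.labeled_sizes:
            labeled, unsup = subsample_labeled(data.target_pool, size, seed)
            if scenario.max_unsup is not None and len(unsup) > scenario.max_unsup:
                unsup = Corpus(
                    list(unsup)[: scenario.max_unsup], name=unsup.name
                )
            for use_pre in pre_arms:
                init = pretrained if use_pre else None
                for use_st in st_arms:
                    if not use_st:
                        result = finetune(
                            init, labeled, seed, scenario.tagger, vocabulary=vocab
                        )
                        rows.append(
                            _row(seed, size, use_pre, False, None, None,
                                 _report(result.tagger, data.test))
                        )
                        continue
                    for threshold in scenario.thresholds:
                        st_cfg = SelfTrainConfig(
                            confidence_threshold=threshold,
                            max_iterations=scenario.max_iterations,
                        )
                        tagger, recs = self_train(
                            init, labeled, unsup, st_cfg, seed,
                            scenario.tagger, vocabulary=vocab,
                        )
                        histories[(size, seed, use_pre, threshold)] = recs
                        rows.append(
                            _row(seed, size, use_pre, True, threshold,
                                 len(recs), _report(tagger, data.test))
                        )
        if scenario.include_fully_supervised:
            result = finetune(
                None, data.target_pool, seed, scenario.tagger, vocabulary=vocab
            )
            rows.append(
                _row(seed, len(data.target_pool), False, False, None, None,
                     _report(result.tagger, data.test), fully_supervised=True)
            )
    return ScenarioResults(table=pd.DataFrame(rows), histories=histories)


def _row(
    seed: int,
    size: int,
    use_pre: bool,
    use_st: bool,
    threshold: float | None,
    n_iterations: int | None,
    report: MetricReport,
    fully_supervised: bool = False,
) -> dict:
    row = {
        "seed": seed,
        "labeled_size": size,
        "pretrain": use_pre,
        "selftrain": use_st,
        "threshold": float("nan") if threshold is None else float(threshold),
        "n_iterations": float("nan") if n_iterations is None else float(n_iterations),
        "fully_supervised": fully_supervised,
    }
    row.update(report.as_dict())
    return row
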
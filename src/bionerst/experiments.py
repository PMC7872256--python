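"""Desk-scale experimental designs mirroring the study's main analyses.

``run_directional_study`` executes, on one synthetic source/target pair and
a set of seeds, the comparisons that carry the study's qualitative
findings:

(a) pre-training + fine-tuning beats fine-tuning alone at 250 labeled
    sentences;
(b) adding self-training raises exact-F1 at 250 and 500 labeled sentences;
(c) exact-F1 is non-decreasing in the labeled-set size over
    {250, 500, 1000, 2000};
(d) lowering the confidence threshold (0.9975 -> 0.9) reduces the number of
    self-training iterations.

Each claim is decided by majority vote over the seeds.  The self-training
arms run on a capped unsupervised set and iteration budget so a full study
fits on one CPU; the fine-tuning-only arms use the full 2000-sentence
target pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .synthetic import StudyData, make_study_data
from .tagger import CrfTagger, TaggerConfig
from .workflow import ScenarioConfig, run_scenario

STUDY_SIZES = (250, 500, 1000, 2000)
SELFTRAIN_SIZES = (250, 500)
SWEEP_THRESHOLDS = (0.9975, 0.9)
#: caps that keep a 5-seed study within a desk-scale compute budget
STUDY_MAX_ITERATIONS = 3
STUDY_MAX_UNSUP = 750


@dataclass
class DirectionalStudy:
    table: pd.DataFrame
    votes: dict[str, float]
    summary: dict[str, float]
    data: StudyData = field(repr=False)


def _f1(table: pd.DataFrame, seed: int, size: int, pre: bool, st: bool) -> float:
    sel = table[
        (table.seed == seed)
        & (table.labeled_size == size)
        & (table.pretrain == pre)
        & (table.selftrain == st)
    ]
    if st:
        sel = sel[sel.threshold == 0.9975]
    return float(sel.exact_f1.iloc[0])


def run_directional_study(
    base_seed: int,
    n_seeds: int = 5,
    tagger: TaggerConfig | None = None,
    data: StudyData | None = None,
) -> DirectionalStudy:
    if tagger is None:
        tagger = TaggerConfig.desk_scale()
    if data is None:
        data = make_study_data(seed=base_seed)
    seeds = tuple(base_seed + i for i in range(n_seeds))
    cache: dict[int, CrfTagger] = {}

    # learning curve with pre-training, all sizes, no self-training
    curve = run_scenario(
        ScenarioConfig(
            labeled_sizes=STUDY_SIZES,
            seeds=seeds,
            use_pretrain=True,
            use_selftrain=False,
            tagger=tagger,
        ),
        data,
        pretrained_cache=cache,
    )
    # no-pretrain baseline at the smallest size
    baseline = run_scenario(
        ScenarioConfig(
            labeled_sizes=(250,),
            seeds=seeds,
            use_pretrain=False,
            use_selftrain=False,
            tagger=tagger,
        ),
        data,
        pretrained_cache=cache,
    )
    # self-training arms at the two smallest sizes, default threshold
    selftrain = run_scenario(
        ScenarioConfig(
            labeled_sizes=SELFTRAIN_SIZES,
            seeds=seeds,
            use_pretrain=True,
            use_selftrain=True,
            thresholds=(SWEEP_THRESHOLDS[0],),
            max_iterations=STUDY_MAX_ITERATIONS,
            max_unsup=STUDY_MAX_UNSUP,
            tagger=tagger,
        ),
        data,
        pretrained_cache=cache,
    )
    # threshold sweep arm (lower threshold) at 250 labeled
    sweep = run_scenario(
        ScenarioConfig(
            labeled_sizes=(250,),
            seeds=seeds,
            use_pretrain=True,
            use_selftrain=True,
            thresholds=(SWEEP_THRESHOLDS[1],),
            max_iterations=STUDY_MAX_ITERATIONS,
            max_unsup=STUDY_MAX_UNSUP,
            tagger=tagger,
        ),
        data,
        pretrained_cache=cache,
    )

    table = pd.concat(
        [curve.table, baseline.table, selftrain.table, sweep.table],
        ignore_index=True,
    )

    votes_a, votes_b250, votes_b500, votes_c, votes_d = [], [], [], [], []
    for seed in seeds:
        votes_a.append(
            _f1(table, seed, 250, True, False) > _f1(table, seed, 250, False, False)
        )
        votes_b250.append(
            _f1(table, seed, 250, True, True) > _f1(table, seed, 250, True, False)
        )
        votes_b500.append(
            _f1(table, seed, 500, True, True) > _f1(table, seed, 500, True, False)
        )
        chain = [_f1(table, seed, s, True, False) for s in STUDY_SIZES]
        votes_c.append(all(b >= a for a, b in zip(chain, chain[1:])))
        n_hi = len(selftrain.histories[(250, seed, True, SWEEP_THRESHOLDS[0])])
        n_lo = len(sweep.histories[(250, seed, True, SWEEP_THRESHOLDS[1])])
        votes_d.append(n_lo < n_hi)

    def frac(v: list[bool]) -> float:
        return sum(v) / len(v)

    votes = {
        "pretrain_beats_plain_at_250": frac(votes_a),
        "selftrain_gain_at_250": frac(votes_b250),
        "selftrain_gain_at_500": frac(votes_b500),
        "f1_monotone_in_labeled_size": frac(votes_c),
        "lower_threshold_fewer_iterations": frac(votes_d),
    }

    def mean_f1(size: int, pre: bool, st: bool) -> float:
        vals = [_f1(table, s, size, pre, st) for s in seeds]
        return sum(vals) / len(vals)

    summary = {
        "mean_exact_f1_finetune_only_250": mean_f1(250, False, False),
        "mean_exact_f1_pretrain_finetune_250": mean_f1(250, True, False),
        "mean_exact_f1_pretrain_finetune_selftrain_250": mean_f1(250, True, True),
        "mean_exact_f1_pretrain_finetune_500": mean_f1(500, True, False),
        "mean_exact_f1_pretrain_finetune_selftrain_500": mean_f1(500, True, True),
        "mean_exact_f1_pretrain_finetune_1000": mean_f1(1000, True, False),
        "mean_exact_f1_pretrain_finetune_2000": mean_f1(2000, True, False),
        "mean_iterations_threshold_0.9975": sum(
            len(selftrain.histories[(250, s, True, SWEEP_THRESHOLDS[0])])
            for s in seeds
        )
        / len(seeds),
        "mean_iterations_threshold_0.9": sum(
            len(sweep.histories[(250, s, True, SWEEP_THRESHOLDS[1])]) for s in seeds
        )
        / len(seeds),
    }
    return DirectionalStudy(table=table, votes=votes, summary=summary, data=data)
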
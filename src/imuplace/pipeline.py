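"""End-to-end convenience runs: simulate -> assemble -> evaluate -> select.

The scaled-down recovery profile evaluates a handful of informative
combinations (wrist-only, trunk-only, the two best leg pairs, all six
locations) under the 50-epoch training profile with leakage-safe grouped
splits, using 3 of the 90 (test, validation) fold pairs per combination —
a single-CPU-friendly slice of the full protocol that still exposes the
planted placement structure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .core import IMUTrial, WalkPatternDataset, assemble_dataset, get_combination
from .evaluate import (
    EvaluationReport,
    SelectionReport,
    evaluate_combination,
    make_cv_splits,
    select_minimal_combinations,
)
from .network import TEST_PROFILE, TrainingConfig
from .simulate import FilterSpec, GaitSimConfig, generate_trials

__all__ = ["RECOVERY_COMB_NUMS", "recovery_run", "RecoveryResult"]

#: wrist-only, trunk-only, shank+shank, right thigh+right shank, all six
RECOVERY_COMB_NUMS = (2, 1, 21, 20, 63)


@dataclasses.dataclass
class RecoveryResult:
    reports: dict[int, EvaluationReport]
    selection: SelectionReport


def recovery_run(
    seed: int = 0,
    comb_nums: Sequence[int] = RECOVERY_COMB_NUMS,
    n_splits: int = 3,
    epochs: int = TEST_PROFILE.epochs,
    trials: Sequence[IMUTrial] | None = None,
) -> RecoveryResult:
    """Evaluate selected combinations on default synthetic data.

    Uses the full emulated design (10 participants x 6 trials x 7
    surfaces), no rotation augmentation, 10 class-stratified folds grouped
    by source trial, and the first ``n_splits`` ordered (test, val) pairs.
    """
    if trials is None:
        trials = generate_trials(GaitSimConfig(seed=seed), FilterSpec())
    cfg = dataclasses.replace(TEST_PROFILE, epochs=epochs, seed=seed)
    reports: dict[int, EvaluationReport] = {}
    for num in comb_nums:
        ds = assemble_dataset(trials, get_combination(num))
        splits = make_cv_splits(ds, n_folds=10, seed=seed, grouping="by_source_trial")
        reports[num] = evaluate_combination(ds, splits[:n_splits], cfg, seed=seed)
    return RecoveryResult(
        reports=reports,
        selection=select_minimal_combinations(list(reports.values())),
    )
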
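"""Cross-validation protocol, confusion-matrix metrics, and sensor-set selection.

The evaluation protocol partitions a combination's walk-pattern dataset
once into 10 class-stratified folds and then enumerates every ordered
(test fold, validation fold) pair — 10*9 = 90 splits at 80/10/10
train/validation/test proportions.  Per split a classifier is trained and
its test confusion matrix recorded; performance is summarized as mean +/- SD
classification accuracy (CA, trace over total) and per-surface correct
classification rate (CCR, per-class recall).  A combination *passes* when
its mean CCR exceeds 90% on every one of the seven surfaces; the selection
step reports the passing combinations of minimal cardinality, ranked by
mean CA.

A leakage-safe grouped mode keeps all augmented copies of one source trial
inside one fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import CombinationSpec, SurfaceClass, WalkPatternDataset
from .network import (
    TEST_PROFILE,
    TrainingConfig,
    build_network,
    predict,
    train,
)

__all__ = [
    "FoldSplit",
    "make_cv_splits",
    "confusion_matrix",
    "classification_accuracy",
    "per_class_ccr",
    "EvaluationReport",
    "evaluate_combination",
    "SelectionReport",
    "select_minimal_combinations",
    "default_train_fn",
]

PASS_CCR_PCT = 90.0


@dataclass
class FoldSplit:
    """One (test fold, validation fold) assignment; the other 8 folds train."""

    fold_assignment: np.ndarray  # pattern index -> fold 0..n_folds-1
    test_fold: int
    val_fold: int

    @property
    def n_folds(self) -> int:
        return int(self.fold_assignment.max()) + 1

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == self.test_fold)

    @property
    def val_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == self.val_fold)

    @property
    def train_indices(self) -> np.ndarray:
        mask = (self.fold_assignment != self.test_fold) & (
            self.fold_assignment != self.val_fold
        )
        return np.flatnonzero(mask)


def _stratified_folds(
    y: np.ndarray, groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each pattern to a fold, stratified by class.

    Patterns sharing a group id (augmented copies of one source trial) are
    assigned as one unit; every group carries a single class by
    construction.
    """
    assignment = np.full(y.shape[0], -1, dtype=np.int64)
    for cls in np.unique(y):
        cls_groups = np.unique(groups[y == cls])
        if len(cls_groups) < n_folds:
            raise ValueError(
                f"class {cls} has {len(cls_groups)} source trials, "
                f"fewer than n_folds={n_folds}"
            )
        if len(cls_groups) % n_folds != 0:
            warnings.warn(
                f"class {cls} count {len(cls_groups)} not divisible by "
                f"{n_folds}; folds will be near-equal",
                stacklevel=3,
            )
        cls_groups = rng.permutation(cls_groups)
        for i, g in enumerate(cls_groups):
            assignment[groups == g] = i % n_folds
    return assignment


def make_cv_splits(
    dataset: WalkPatternDataset,
    n_folds: int = 10,
    seed: int = 0,
    grouping: str = "none",
) -> list[FoldSplit]:
    """Build the n*(n-1) ordered (test, validation) splits of one partition.

    ``grouping='none'`` stratifies individual patterns (augmented siblings
    of one trial may straddle folds, as in the original protocol);
    ``'by_source_trial'`` keeps them together (leakage-safe).
    """
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3 (train/val/test all non-empty)")
    _, y = dataset.stack()
    if grouping == "none":
        groups = np.arange(len(y))
    elif grouping == "by_source_trial":
        groups = dataset.group_ids()
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(y, groups, n_folds, rng)
    return [
        FoldSplit(fold_assignment=assignment, test_fold=i, val_fold=j)
        for i in range(n_folds)
        for j in range(n_folds)
        if i != j
    ]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 7
) -> np.ndarray:
    """counts[i, j] = patterns of true class i predicted as class j."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def classification_accuracy(cm: np.ndarray) -> float:
    """CA in percent: trace over total."""
    total = cm.sum()
    return float(np.trace(cm) / total * 100.0) if total else 0.0


def per_class_ccr(cm: np.ndarray) -> np.ndarray:
    """Per-class recall in percent; empty rows give NaN."""
    row = cm.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, np.diag(cm) / row * 100.0, np.nan)


@dataclass
class EvaluationReport:
    combination: CombinationSpec
    confusion_matrices: list[np.ndarray]
    ca_per_split: np.ndarray  # percent
    ccr_per_split: np.ndarray  # (n_splits, 7), percent

    @property
    def mean_ca(self) -> float:
        return float(self.ca_per_split.mean())

    @property
    def sd_ca(self) -> float:
        return float(self.ca_per_split.std(ddof=1)) if len(self.ca_per_split) > 1 else 0.0

    @property
    def mean_ccr(self) -> np.ndarray:
        return self.ccr_per_split.mean(axis=0)

    @property
    def sd_ccr(self) -> np.ndarray:
        if self.ccr_per_split.shape[0] > 1:
            return self.ccr_per_split.std(axis=0, ddof=1)
        return np.zeros(self.ccr_per_split.shape[1])

    @property
    def pass_flag(self) -> bool:
        """True when the mean CCR exceeds 90% on every surface."""
        return bool(np.all(self.mean_ccr > PASS_CCR_PCT))

    def summary(self) -> dict:
        return {
            "comb_num": self.combination.comb_num,
            "locations": [l.value for l in self.combination.locations],
            "n_locations": self.combination.n_locations,
            "mean_ca_pct": round(self.mean_ca, 2),
            "sd_ca_pct": round(self.sd_ca, 2),
            "mean_ccr_pct": {
                s.value: round(float(v), 2)
                for s, v in zip(SurfaceClass, self.mean_ccr)
            },
            "sd_ccr_pct": {
                s.value: round(float(v), 2) for s, v in zip(SurfaceClass, self.sd_ccr)
            },
            "pass": self.pass_flag,
        }


def default_train_fn(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    config: TrainingConfig,
    seed: int,
) -> Callable[[np.ndarray], np.ndarray]:
    """Train the causal CNN on one split; returns a predictor.

    Inputs are standardized per channel with statistics fitted on the
    training portion only.
    """
    mu = Xtr.mean(axis=(0, 2), keepdims=True)
    sd = Xtr.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd < 1e-8, 1.0, sd)

    def norm(X: np.ndarray) -> np.ndarray:
        return ((X - mu) / sd).astype(np.float32)

    model = build_network(Xtr.shape[1], seed=seed)
    train(model, norm(Xtr), ytr, norm(Xval), yval, config)
    return lambda X: predict(model, norm(X))[0]


def evaluate_combination(
    dataset: WalkPatternDataset,
    splits: Sequence[FoldSplit],
    training_config: TrainingConfig = TEST_PROFILE,
    train_fn: Callable = default_train_fn,
    seed: int = 0,
) -> EvaluationReport:
    """Train and score one classifier per split; aggregate CA and CCR."""
    X, y = dataset.stack()
    cms, cas, ccrs = [], [], []
    for s_idx, split in enumerate(splits):
        tr, va, te = split.train_indices, split.val_indices, split.test_indices
        try:
            predict_fn = train_fn(
                X[tr], y[tr], X[va], y[va], training_config, seed + s_idx
            )
            y_pred = predict_fn(X[te])
        except Exception as exc:
            raise RuntimeError(
                f"training failed on split (test={split.test_fold}, "
                f"val={split.val_fold}) of combination "
                f"{dataset.combination.comb_num}"
            ) from exc
        cm = confusion_matrix(y[te], y_pred)
        cms.append(cm)
        cas.append(classification_accuracy(cm))
        ccrs.append(per_class_ccr(cm))
    return EvaluationReport(
        combination=dataset.combination,
        confusion_matrices=cms,
        ca_per_split=np.asarray(cas),
        ccr_per_split=np.asarray(ccrs),
    )


@dataclass
class SelectionReport:
    """Passing combinations grouped by cardinality, minimal set first."""

    reports: list[EvaluationReport]
    passing: list[EvaluationReport] = field(init=False)
    minimal_cardinality: int | None = field(init=False)
    best: list[EvaluationReport] = field(init=False)

    def __post_init__(self) -> None:
        self.passing = [r for r in self.reports if r.pass_flag]
        if self.passing:
            self.minimal_cardinality = min(
                r.combination.n_locations for r in self.passing
            )
            self.best = sorted(
                (
                    r
                    for r in self.passing
                    if r.combination.n_locations == self.minimal_cardinality
                ),
                key=lambda r: -r.mean_ca,
            )
        else:
            self.minimal_cardinality = None
            self.best = []

    def passes_by_cardinality(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.passing:
            out[r.combination.n_locations] = out.get(r.combination.n_locations, 0) + 1
        return dict(sorted(out.items()))

    def summary(self) -> dict:
        return {
            "n_evaluated": len(self.reports),
            "n_passing": len(self.passing),
            "passes_by_cardinality": self.passes_by_cardinality(),
            "minimal_cardinality": self.minimal_cardinality,
            "best": [r.summary() for r in self.best],
            "all": [r.summary() for r in self.reports],
            "note": (
                None
                if self.passing
                else "no combination satisfies the all-surface CCR>90% criterion"
            ),
        }


def select_minimal_combinations(reports: Sequence[EvaluationReport]) -> SelectionReport:
    """Apply the all-surface CCR > 90% rule and rank minimal passing sets."""
    return SelectionReport(reports=list(reports))
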
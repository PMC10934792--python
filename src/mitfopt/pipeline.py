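"""End-to-end decoding pipeline.

The procedure: split the data into a training and a held-out test
partition (stratified, default 7:3); run the sparrow search over
time-frequency segments, scoring each candidate by five-fold
cross-validated accuracy of the channel-selection + RCSP + SVM decoder on
the training partition only; then, with the winning segment, train the
final decoder (full C/gamma grid) on the whole training partition and
report accuracy on the held-out partition.

Within every cross-validation fold the channel selection and the spatial
filters are computed on that fold's training part alone, so no validation
information leaks into the decoder.  The held-out partition is wrapped in
an access guard that records every read; a correct run reads it exactly
once, after the optimization has finished.

Candidate segments that leave too few samples or channels to fit the
decoder receive the worst fitness (1.0) instead of raising, keeping the
optimizer total over its search box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import ccs as ccs_mod
from . import classify, rcsp, ssa
from .io_fixture import FAST_GRID, EpochSet, RunConfig
from .tfsegment import TimeFreqSegment, apply_segment, decode_position

__all__ = [
    "PipelineResult",
    "ComparisonResult",
    "TestPartitionGuard",
    "fitness",
    "evaluate_segment",
    "run",
    "compare_noncustom",
    "FIXED_SEGMENT",
]

logger = logging.getLogger("mitfopt")

# Non-customized reference segment: 0-4 s window, 8-30 Hz band (the joint
# alpha+beta band conventionally used when no per-subject tuning is done).
FIXED_SEGMENT = TimeFreqSegment(fstart=8.0, fwidth=22.0, tstart=0.0, twidth=4.0)


class TestPartitionGuard:
    """Wraps the held-out partition and audits access to it.

    ``read()`` is the only way to reach the wrapped epochs; each call
    records whether optimization had already completed.  The pipeline
    asserts exactly one read, after optimization.
    """

    __test__ = False  # not a test class despite the name

    def __init__(self, epochs: EpochSet):
        self.__epochs = epochs
        self.optimization_complete = False
        self.reads: list = []  # True if the read happened after optimization

    def read(self) -> EpochSet:
        self.reads.append(self.optimization_complete)
        return self.__epochs

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def all_reads_after_optimization(self) -> bool:
        return all(self.reads)

    def audit(self) -> dict:
        return {
            "test_partition_reads": self.n_reads,
            "all_reads_after_optimization": self.all_reads_after_optimization,
        }


@dataclass
class PipelineResult:
    best_segment: TimeFreqSegment
    selected_channels: list
    final_classifier: classify.TrainedClassifier
    test_accuracy: float
    history: np.ndarray
    config: RunConfig
    seed: int
    n_fitness_evaluations: int
    n_unique_segments: int
    leakage_audit: dict = field(default_factory=dict)
    rcsp_model: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "best_segment": self.best_segment.to_dict(),
            "selected_channels": list(self.selected_channels),
            "svm": {
                "C": self.final_classifier.C,
                "g": self.final_classifier.g,
                "cv_accuracy": self.final_classifier.cv_accuracy,
                "folds": self.final_classifier.folds,
            },
            "test_accuracy": self.test_accuracy,
            "history": [float(h) for h in self.history],
            "seed": self.seed,
            "n_fitness_evaluations": self.n_fitness_evaluations,
            "n_unique_segments": self.n_unique_segments,
            "leakage_audit": self.leakage_audit,
            "config": self.config.to_dict(),
            "result_schema_version": 1,
        }


@dataclass
class ComparisonResult:
    optimized_segment: TimeFreqSegment
    fixed_segment: TimeFreqSegment
    optimized_accuracy: float
    fixed_accuracy: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "optimized_segment": self.optimized_segment.to_dict(),
            "fixed_segment": self.fixed_segment.to_dict(),
            "optimized_accuracy": self.optimized_accuracy,
            "fixed_accuracy": self.fixed_accuracy,
            "seed": self.seed,
        }


def _derive_seeds(seed: int) -> tuple:
    """Split / optimizer / cross-validation seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(3)
    return tuple(int(s % 2**31) for s in state)


def fitness(
    segment: TimeFreqSegment,
    train_set: EpochSet,
    config: Optional[RunConfig] = None,
    seed: int = 0,
) -> float:
    """1 - mean cross-validated accuracy of the decoder on a segment.

    Five stratified folds; per fold: channel selection on the training
    part, RCSP fit on the training part, SVM trained per (C, gamma) pair of
    the inner grid and scored on the validation part.  The returned fitness
    is 1 minus the best pair's mean fold accuracy, so lower is better and
    chance-level decoding gives about 0.5.  Degenerate segments score 1.0.
    """
    config = config or RunConfig()
    try:
        segmented = apply_segment(train_set, segment)
    except ValueError as exc:
        logger.warning("segment %s rejected: %s", segment, exc)
        return 1.0
    if segmented.n_samples < 2:
        logger.warning("segment %s leaves < 2 samples", segment)
        return 1.0

    C_grid = FAST_GRID if config.svm.fast_grid else config.svm.C_grid
    g_grid = FAST_GRID if config.svm.fast_grid else config.svm.g_grid
    C_grid = sorted(C_grid)
    g_grid = sorted(g_grid)

    skf = StratifiedKFold(n_splits=config.svm.k, shuffle=True, random_state=seed)
    acc = np.zeros((len(C_grid), len(g_grid), config.svm.k))
    try:
        fold_dummy = np.zeros((segmented.n_trials, 1))
        for fold, (tr_idx, va_idx) in enumerate(skf.split(fold_dummy, segmented.labels)):
            d_train = segmented.select_trials(tr_idx)
            d_valid = segmented.select_trials(va_idx)
            selection = ccs_mod.select_channels(
                d_train,
                n_select=config.ccs.n_select,
                n_trials=config.ccs.n_trials,
                exclude_diagonal=config.ccs.exclude_diagonal,
            )
            if len(selection.selected) < 2 * config.rcsp.m:
                logger.warning("segment %s leaves < 2m channels after selection", segment)
                return 1.0
            d_train = d_train.select_channels(selection.selected)
            d_valid = d_valid.select_channels(selection.selected)
            model = rcsp.fit(d_train, m=config.rcsp.m, alpha=config.rcsp.alpha, beta=config.rcsp.beta)
            f_train = rcsp.transform(model, d_train)
            f_valid = rcsp.transform(model, d_valid)
            for ci, C in enumerate(C_grid):
                for gi, g in enumerate(g_grid):
                    clf = classify.make_svm(C, g, config.svm.standardize)
                    clf.fit(f_train, d_train.labels)
                    acc[ci, gi, fold] = clf.score(f_valid, d_valid.labels)
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("segment %s failed during fitness evaluation: %s", segment, exc)
        return 1.0

    mean_acc = acc.mean(axis=-1)  # per (C, g) pair; grids sorted so argmax
    best_acc = float(mean_acc.max())  # ties resolve to smallest C then g via first argmax
    return 1.0 - best_acc


def evaluate_segment(
    segment: TimeFreqSegment,
    train_set: EpochSet,
    test_set: EpochSet,
    config: Optional[RunConfig] = None,
    seed: int = 0,
):
    """Train the final decoder on a segment and score the held-out set.

    Channel selection and spatial filters come from the training set alone;
    the SVM uses the full C/gamma grids regardless of the fast-grid flag.
    Returns ``(accuracy, classifier, selected channel names, rcsp model)``.
    """
    config = config or RunConfig()
    seg_train = apply_segment(train_set, segment)
    seg_test = apply_segment(test_set, segment)
    selection = ccs_mod.select_channels(
        seg_train,
        n_select=config.ccs.n_select,
        n_trials=config.ccs.n_trials,
        exclude_diagonal=config.ccs.exclude_diagonal,
    )
    seg_train = seg_train.select_channels(selection.selected)
    seg_test = seg_test.select_channels(selection.selected)
    model = rcsp.fit(seg_train, m=config.rcsp.m, alpha=config.rcsp.alpha, beta=config.rcsp.beta)
    f_train = rcsp.transform(model, seg_train)
    f_test = rcsp.transform(model, seg_test)
    clf = classify.grid_search_cv(
        f_train,
        seg_train.labels,
        C_grid=config.svm.C_grid,
        g_grid=config.svm.g_grid,
        k=config.svm.k,
        seed=seed,
        standardize=config.svm.standardize,
    )
    accuracy = classify.evaluate(clf, f_test, seg_test.labels)
    return accuracy, clf, list(seg_train.channel_names), model


def _split(dataset: EpochSet, config: RunConfig, split_seed: int):
    idx = np.arange(dataset.n_trials)
    stratify = dataset.labels if config.split.stratified else None
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - config.split.train_fraction,
        stratify=stratify,
        random_state=split_seed,
        shuffle=True,
    )
    return dataset.select_trials(np.sort(train_idx)), dataset.select_trials(np.sort(test_idx))


def _optimize_segment(train_set: EpochSet, config: RunConfig, ssa_seed: int, cv_seed: int):
    """Run the sparrow search over segments; returns (result, cache size)."""
    cache: dict = {}

    def objective(position: np.ndarray) -> float:
        key = tuple(np.round(position, 6))
        if key not in cache:
            seg = decode_position(position, config.bounds)
            cache[key] = fitness(seg, train_set, config, seed=cv_seed)
        return cache[key]

    ssa_config = ssa.SSAConfig(
        n=config.ssa.n,
        itermax=config.ssa.itermax,
        producer_ratio=config.ssa.producer_ratio,
        scout_ratio=config.ssa.scout_ratio,
        seed=ssa_seed,
    )
    result = ssa.optimize(objective, ssa_config, d=4)
    return result, len(cache)


def run(dataset: EpochSet, config: Optional[RunConfig] = None, seed: Optional[int] = None) -> PipelineResult:
    """Full pipeline: split, optimize the segment, train and score the decoder."""
    config = config or RunConfig()
    dataset.validate(require_two_classes=True)
    if seed is None:
        seed = config.ssa.seed
    split_seed, ssa_seed, cv_seed = _derive_seeds(seed)

    train_set, test_set = _split(dataset, config, split_seed)
    guard = TestPartitionGuard(test_set)
    del test_set  # only reachable through the guard from here on

    result, n_unique = _optimize_segment(train_set, config, ssa_seed, cv_seed)
    guard.optimization_complete = True
    best_segment = decode_position(result.best_position, config.bounds)

    held_out = guard.read()
    accuracy, clf, channel_names, model = evaluate_segment(
        best_segment, train_set, held_out, config, cv_seed
    )

    return PipelineResult(
        best_segment=best_segment,
        selected_channels=channel_names,
        final_classifier=clf,
        test_accuracy=accuracy,
        history=result.history,
        config=config,
        seed=seed,
        n_fitness_evaluations=result.n_evaluations,
        n_unique_segments=n_unique,
        leakage_audit=guard.audit(),
        rcsp_model=model,
    )


def compare_noncustom(
    dataset: EpochSet, config: Optional[RunConfig] = None, seed: Optional[int] = None
) -> ComparisonResult:
    """Paired contrast: optimized segment versus the fixed 0-4 s / 8-30 Hz one.

    Both arms share the same train/test split, cross-validation folds and
    SVM grids, so the accuracy difference isolates the effect of segment
    customization.
    """
    config = config or RunConfig()
    dataset.validate(require_two_classes=True)
    if seed is None:
        seed = config.ssa.seed
    split_seed, ssa_seed, cv_seed = _derive_seeds(seed)

    train_set, test_set = _split(dataset, config, split_seed)
    result, _ = _optimize_segment(train_set, config, ssa_seed, cv_seed)
    optimized = decode_position(result.best_position, config.bounds)

    fixed = FIXED_SEGMENT
    # clamp the fixed window to the data extent so short epochs still work
    t_lo = max(fixed.tstart, train_set.t0)
    t_hi = min(fixed.tstop, train_set.t0 + train_set.n_samples / train_set.sfreq)
    fixed = TimeFreqSegment(fixed.fstart, fixed.fwidth, t_lo, t_hi - t_lo)

    opt_acc, _, _, _ = evaluate_segment(optimized, train_set, test_set, config, cv_seed)
    fix_acc, _, _, _ = evaluate_segment(fixed, train_set, test_set, config, cv_seed)
    return ComparisonResult(
        optimized_segment=optimized,
        fixed_segment=fixed,
        optimized_accuracy=opt_acc,
        fixed_accuracy=fix_acc,
        seed=seed,
    )
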
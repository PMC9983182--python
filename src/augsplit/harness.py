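"""Training harness: mini-batch epochs, validation-gated early stopping,
and per-fold measurement collection.

The schedule mirrors common deep-learning practice for small datasets:
mini-batches of 10 images, momentum SGD with a small learning rate and L2
penalty, the training set reshuffled at the start of every epoch, the
validation set scored after every epoch, and training stopped once a fixed
number of consecutive epochs (the *patience*) fails to improve the best
validation accuracy seen so far, or when the epoch cap is reached.  The
model finally returned is the best-validation-accuracy checkpoint.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from ._rng import derive_rng, derive_seed
from .augment import augment_dataset
from .dataset import LabeledDataset, label_vector, stack_pixels
from .protocols import ProtocolConfig, build_fold_datasets

__all__ = [
    "TrainingConfig",
    "ContractError",
    "ConfusionCounts",
    "TestEvaluation",
    "FoldResult",
    "train_with_early_stopping",
    "evaluate_on_test",
    "run_experiment",
    "PLAIN_TEST",
    "AUGMENTED_TEST",
]

PLAIN_TEST = "plain"
AUGMENTED_TEST = "augmented"


class ContractError(RuntimeError):
    """A classifier violated the probability contract."""


@dataclass(frozen=True)
class TrainingConfig:
    """Mini-batch training schedule.

    Defaults: batches of 10 images, momentum-SGD with learning rate 1e-4,
    momentum 0.9 and L2 factor 1e-4, at most 50 epochs with a patience of 5,
    and a classification threshold of 0.5.
    """

    minibatch_size: int = 10
    learning_rate: float = 1e-4
    momentum: float = 0.9
    l2_factor: float = 1e-4
    max_epochs: int = 50
    patience: int = 5
    classification_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.classification_threshold < 1.0:
            raise ValueError("classification_threshold must be in (0, 1)")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("patience must satisfy 0 < patience < max_epochs")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass
class TestEvaluation:
    """Per-record probabilities plus the thresholded confusion counts."""

    confusion: ConfusionCounts
    probabilities: np.ndarray
    labels: np.ndarray
    image_ids: list[str]


@dataclass
class FoldResult:
    """Everything the statistics layer needs about one trained fold."""

    fold: int
    epoch_count: int
    best_epoch: int
    training_time: float
    validation_successes: int
    validation_trials: int
    validation_trace: list[float]
    tests: dict[str, TestEvaluation] = field(default_factory=dict)

    @property
    def validation_accuracy(self) -> float:
        return self.validation_successes / self.validation_trials


def _checked_proba(clf, X: np.ndarray) -> np.ndarray:
    p = np.asarray(clf.predict_proba(X), dtype=np.float64)
    if p.shape != (X.shape[0],):
        raise ContractError(f"predict_proba returned shape {p.shape}, "
                            f"expected ({X.shape[0]},)")
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ContractError("predict_proba returned values outside [0, 1]")
    return p


def train_with_early_stopping(
    clf,
    train: LabeledDataset,
    validation: LabeledDataset,
    cfg: TrainingConfig,
) -> FoldResult:
    """Train until the validation accuracy stalls for ``patience`` epochs.

    After each epoch the validation accuracy at the classification threshold
    is computed; an epoch *improves* the model only if it strictly exceeds
    the best accuracy seen so far.  Training stops after ``patience``
    consecutive non-improving epochs or at ``max_epochs``, whichever comes
    first, and the classifier is restored to the best checkpoint.  Returns a
    :class:`FoldResult` without test evaluations (``fold`` set to 0).
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if len(set(validation.labels)) < 2:
        raise ValueError("validation set must contain both classes")

    Xtr, ytr = stack_pixels(train), label_vector(train)
    Xva, yva = stack_pixels(validation), label_vector(validation)
    thr = cfg.classification_threshold

    best_acc = -np.inf
    best_state = None
    best_successes = 0
    best_epoch = 0
    since_improved = 0
    trace: list[float] = []

    t0 = time.perf_counter()
    epoch = 0
    while epoch < cfg.max_epochs:
        epoch += 1
        order = derive_rng(cfg.seed, "epoch", epoch).permutation(len(ytr))
        clf.train_epoch(Xtr, ytr, order, cfg)
        p = _checked_proba(clf, Xva)
        successes = int(((p >= thr).astype(int) == yva).sum())
        acc = successes / len(yva)
        trace.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_state = clf.get_state()
            best_successes = successes
            best_epoch = epoch
            since_improved = 0
        else:
            since_improved += 1
        if since_improved >= cfg.patience:
            break
    elapsed = time.perf_counter() - t0

    clf.set_state(best_state)
    return FoldResult(
        fold=0,
        epoch_count=epoch,
        best_epoch=best_epoch,
        training_time=elapsed,
        validation_successes=best_successes,
        validation_trials=len(yva),
        validation_trace=trace,
    )


def evaluate_on_test(clf, test: LabeledDataset, threshold: float = 0.5) -> TestEvaluation:
    """Score a trained model on a test set at the given threshold.

    A probability exactly at the threshold counts as a positive call.
    """
    if len(test) == 0:
        raise ValueError("test set must be nonempty")
    X, y = stack_pixels(test), label_vector(test)
    p = _checked_proba(clf, X)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return TestEvaluation(
        confusion=ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn),
        probabilities=p,
        labels=y,
        image_ids=[r.image_id for r in test],
    )


def run_experiment(
    ds: LabeledDataset,
    cfg: ProtocolConfig,
    tcfg: TrainingConfig,
    classifier_factory,
) -> list[FoldResult]:
    """Run the k folds of one model-building way.

    One model is trained per fold; when the way permits both test
    conditions (ways A-E) the same trained model is evaluated on the
    original test part (``"plain"``) and on its eight-fold augmentation
    (``"augmented"``).  Way F has only its inherently augmented test set.
    ``classifier_factory(image_size, seed)`` must return a fresh classifier.
    """
    results: list[FoldResult] = []
    for fold in range(1, cfg.k + 1):
        if cfg.way == "F":
            train, val, test_aug = build_fold_datasets(ds, cfg, fold)
            test_plain = None
        else:
            base = ProtocolConfig(way=cfg.way, test_augmented=False, k=cfg.k, seed=cfg.seed)
            train, val, test_plain = build_fold_datasets(ds, base, fold)
            test_aug = augment_dataset(test_plain)

        side = train.records[0].pixels.shape[0]
        clf = classifier_factory(side, derive_seed(tcfg.seed, "init", cfg.way, fold))
        fold_tcfg = TrainingConfig(
            minibatch_size=tcfg.minibatch_size,
            learning_rate=tcfg.learning_rate,
            momentum=tcfg.momentum,
            l2_factor=tcfg.l2_factor,
            max_epochs=tcfg.max_epochs,
            patience=tcfg.patience,
            classification_threshold=tcfg.classification_threshold,
            seed=derive_seed(tcfg.seed, "shuffle", cfg.way, fold),
        )
        result = train_with_early_stopping(clf, train, val, fold_tcfg)
        result.fold = fold
        thr = tcfg.classification_threshold
        if test_plain is not None:
            result.tests[PLAIN_TEST] = evaluate_on_test(clf, test_plain, thr)
        result.tests[AUGMENTED_TEST] = evaluate_on_test(clf, test_aug, thr)
        results.append(result)
    return results
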
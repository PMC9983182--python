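"""The replicated placement study and its directional comparisons.

:func:`run_placement_study` repeats the six model-building ways over many
master seeds (fresh synthetic dataset, fresh splits, fresh initialization
per seed) and tabulates, per seed and way, the pooled validation accuracy,
pooled test accuracy under both test conditions, confidence-interval widths
and training effort.  :func:`placement_effects` turns that table into the
paired per-seed differences behind the study's findings, and
:func:`sign_flip_pvalue` tests each difference's direction with an exact
one-sided sign-flip (resampling) test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .classifiers import SmallConvNet
from .evalstats import pooled_proportion_metrics, pooled_roc_auc
from .harness import AUGMENTED_TEST, PLAIN_TEST, TrainingConfig, run_experiment
from .protocols import WAYS, ProtocolConfig
from .synthdata import SynthParams, generate_synthetic_dataset

__all__ = [
    "run_placement_study",
    "placement_effects",
    "sign_flip_pvalue",
]


def _group_stats(folds, condition):
    confs = [f.tests[condition].confusion for f in folds]
    pooled = pooled_proportion_metrics(confs)
    probs = np.concatenate([f.tests[condition].probabilities for f in folds])
    labels = np.concatenate([f.tests[condition].labels for f in folds])
    auc = pooled_roc_auc(probs, labels)
    acc = pooled.accuracy
    return acc, auc


def run_placement_study(
    n_seeds: int = 10,
    params: SynthParams | None = None,
    tcfg: TrainingConfig | None = None,
    classifier_factory=SmallConvNet,
    ways=WAYS,
    k: int = 5,
    base_seed: int = 0,
    progress=None,
) -> pd.DataFrame:
    """Run the six ways over ``n_seeds`` replicate seeds.

    Each replicate draws a fresh synthetic dataset and fresh split/training
    seeds (all derived from ``base_seed``).  Returns a tidy frame with one
    row per (seed, way) carrying pooled validation accuracy, pooled test
    accuracy and ROC AUC under both test conditions, exact-CI widths, and
    mean epochs and training time per fold.
    """
    params = params if params is not None else SynthParams()
    tcfg = tcfg if tcfg is not None else TrainingConfig()
    rows = []
    for rep in range(n_seeds):
        ds = generate_synthetic_dataset(
            params.replace(seed=derive_seed(base_seed, "data", rep))
        )
        split_seed = derive_seed(base_seed, "split", rep)
        train_seed = derive_seed(base_seed, "train", rep)
        for way in ways:
            pcfg = ProtocolConfig(way=way, test_augmented=(way == "F"),
                                  k=k, seed=split_seed)
            wtcfg = TrainingConfig(
                minibatch_size=tcfg.minibatch_size,
                learning_rate=tcfg.learning_rate,
                momentum=tcfg.momentum,
                l2_factor=tcfg.l2_factor,
                max_epochs=tcfg.max_epochs,
                patience=tcfg.patience,
                classification_threshold=tcfg.classification_threshold,
                seed=train_seed,
            )
            folds = run_experiment(ds, pcfg, wtcfg, classifier_factory)
            row = {
                "seed": rep,
                "way": way,
                "validation_accuracy": (
                    sum(f.validation_successes for f in folds)
                    / sum(f.validation_trials for f in folds)
                ),
                "mean_epochs": float(np.mean([f.epoch_count for f in folds])),
                "mean_time_s": float(np.mean([f.training_time for f in folds])),
            }
            for condition, tag in ((PLAIN_TEST, "plain"), (AUGMENTED_TEST, "aug")):
                if condition in folds[0].tests:
                    acc, auc = _group_stats(folds, condition)
                    row[f"test_accuracy_{tag}"] = acc.point
                    row[f"test_ci_width_{tag}"] = acc.ci_width
                    row[f"test_auc_{tag}"] = auc.auc
                else:
                    row[f"test_accuracy_{tag}"] = np.nan
                    row[f"test_ci_width_{tag}"] = np.nan
                    row[f"test_auc_{tag}"] = np.nan
            rows.append(row)
            if progress is not None:
                progress(rep, way, row)
    return pd.DataFrame(rows)


def _per_seed(df: pd.DataFrame, way: str, col: str) -> np.ndarray:
    sub = df[df.way == way].sort_values("seed")
    return sub[col].to_numpy()


def placement_effects(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Paired per-seed differences for the study's directional findings.

    Keys (each an array of per-seed differences, positive = the finding's
    direction):

    - ``F_minus_E_test``: augment-first test accuracy exceeds way E's.
    - ``E_val_minus_test``: way E's validation accuracy exceeds its own
      test accuracy (train/validation leakage inflates validation).
    - ``{C,D,E,F}_val_minus_B_val``: augmenting the training set by any way
      raises validation accuracy.
    - ``B_val_minus_A_val``: augmenting the validation set alone lowers it.
    - ``plain_minus_aug_unaugmented_train``: with an unaugmented training
      set (ways A and B), augmented-test metrics fall below the
      non-augmented-test metrics.
    """
    out: dict[str, np.ndarray] = {}
    out["F_minus_E_test"] = (_per_seed(df, "F", "test_accuracy_aug")
                             - _per_seed(df, "E", "test_accuracy_aug"))
    out["E_val_minus_test"] = (_per_seed(df, "E", "validation_accuracy")
                               - _per_seed(df, "E", "test_accuracy_aug"))
    b_val = _per_seed(df, "B", "validation_accuracy")
    for way in ("C", "D", "E", "F"):
        out[f"{way}_val_minus_B_val"] = _per_seed(df, way, "validation_accuracy") - b_val
    out["B_val_minus_A_val"] = b_val - _per_seed(df, "A", "validation_accuracy")
    plain = 0.5 * (_per_seed(df, "A", "test_accuracy_plain")
                   + _per_seed(df, "B", "test_accuracy_plain"))
    aug = 0.5 * (_per_seed(df, "A", "test_accuracy_aug")
                 + _per_seed(df, "B", "test_accuracy_aug"))
    out["plain_minus_aug_unaugmented_train"] = plain - aug
    return out


def sign_flip_pvalue(diffs, exhaustive_limit: int = 20) -> float:
    """One-sided exact sign-flip test that the mean difference is positive.

    Enumerates all sign assignments (for up to ``exhaustive_limit`` paired
    differences) and returns the fraction of assignments whose mean is at
    least the observed mean.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("no differences supplied")
    if n > exhaustive_limit:
        raise ValueError("exhaustive sign-flip test limited to "
                         f"{exhaustive_limit} pairs, got {n}")
    observed = d.mean()
    count = 0
    total = 2 ** n
    for signs in itertools.product((1.0, -1.0), repeat=n):
        if np.dot(signs, d) / n >= observed - 1e-12:
            count += 1
    return count / total
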
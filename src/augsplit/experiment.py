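"""Experiment-matrix orchestration: classifiers x augmentation ways.

:func:`run_matrix` executes the full study defined by an
:class:`ExperimentConfig`: for every classifier and model-building way it
trains the k cross-validation folds, evaluates each trained model on both
test conditions where permitted, audits leakage, pools the fold statistics,
and computes the time-cost-effectiveness correlations.  The structural
cardinalities of the matrix (6 model-building ways, 11 evaluation
configurations per classifier, 24 model groups and 44 testing groups for
four classifiers) are asserted before any training begins.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .classifiers import PixelLogistic, SmallConvNet
from .dataset import LabeledDataset
from .evalstats import (
    MeanEstimate,
    PooledMetrics,
    TimeCostResult,
    filter_time_cost_groups,
    mean_with_t4_ci,
    pooled_proportion_metrics,
    pooled_roc_auc,
    time_cost_correlation,
)
from .harness import AUGMENTED_TEST, PLAIN_TEST, FoldResult, TrainingConfig, run_experiment
from .protocols import (
    WAYS,
    LeakageReport,
    ProtocolConfig,
    audit_fold,
    build_fold_datasets,
    enumerate_protocols,
)
from .synthdata import SynthParams, generate_synthetic_dataset

__all__ = [
    "CLASSIFIER_REGISTRY",
    "ExperimentConfig",
    "GroupResult",
    "ReportBundle",
    "matrix_cardinalities",
    "run_matrix",
    "summarize",
    "bundle_to_dict",
    "summary_from_dict",
    "write_bundle",
]

#: Built-in classifier factories by name; each maps (image_size, seed) -> model.
CLASSIFIER_REGISTRY = {
    "convnet": SmallConvNet,
    "logistic": PixelLogistic,
}


@dataclass
class ExperimentConfig:
    """Declarative description of one full experiment matrix."""

    synth: SynthParams | None = None
    dataset: LabeledDataset | None = None
    classifiers: dict = field(default_factory=lambda: {"convnet": SmallConvNet})
    ways: tuple = WAYS
    k: int = 5
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    test_conditions_for: str = "all"

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("at least one classifier is required")
        if not self.ways:
            raise ValueError("at least one way is required")
        for w in self.ways:
            if w not in WAYS:
                raise ValueError(f"unknown way {w!r}")
        if self.synth is None and self.dataset is None:
            self.synth = SynthParams(seed=derive_seed(self.seed, "synth"))


def matrix_cardinalities(n_classifiers: int, ways=WAYS) -> dict[str, int]:
    """Structural counts of the experiment matrix before any training."""
    n_ways = len(ways)
    n_eval = sum(1 if w == "F" else 2 for w in ways)
    return {
        "model_building_ways": n_ways,
        "evaluation_configurations": n_eval,
        "model_groups": n_classifiers * n_ways,
        "testing_groups": n_classifiers * n_eval,
    }


@dataclass
class GroupResult:
    """Pooled results of one (classifier, way, test-condition) testing group."""

    classifier: str
    way: str
    test_condition: str
    pooled: PooledMetrics
    epochs: MeanEstimate
    time: MeanEstimate
    validation: PooledMetrics
    leakage: LeakageReport
    fold_results: list[FoldResult] = field(repr=False, default_factory=list)

    def to_row(self) -> dict:
        r = {
            "classifier": self.classifier,
            "way": self.way,
            "test_condition": self.test_condition,
            "n_folds": self.pooled.n_folds,
            "tp": self.pooled.tp, "tn": self.pooled.tn,
            "fp": self.pooled.fp, "fn": self.pooled.fn,
            "mean_epochs": self.epochs.mean,
            "epochs_ci_low": self.epochs.ci_low, "epochs_ci_high": self.epochs.ci_high,
            "mean_time_s": self.time.mean,
            "time_ci_low": self.time.ci_low, "time_ci_high": self.time.ci_high,
            "leak_train_val": self.leakage.parents_train_val,
            "leak_train_test": self.leakage.parents_train_test,
            "leak_val_test": self.leakage.parents_val_test,
        }
        for name in ("accuracy", "sensitivity", "specificity"):
            try:
                est = getattr(self.pooled, name)
                r[name] = est.point
                r[f"{name}_ci_low"], r[f"{name}_ci_high"] = est.ci_low, est.ci_high
            except ZeroDivisionError:
                r[name] = r[f"{name}_ci_low"] = r[f"{name}_ci_high"] = np.nan
        auc = self.pooled.roc_auc
        r["roc_auc"] = auc.auc if auc else np.nan
        r["roc_auc_ci_low"] = auc.ci_low if auc else np.nan
        r["roc_auc_ci_high"] = auc.ci_high if auc else np.nan
        va = self.validation.accuracy
        r["validation_accuracy"] = va.point
        r["validation_ci_low"], r["validation_ci_high"] = va.ci_low, va.ci_high
        return r


@dataclass
class ReportBundle:
    """Everything :func:`run_matrix` produces."""

    groups: list[GroupResult]
    timecost: list[TimeCostResult]
    cardinalities: dict[str, int]
    seeds: dict[str, int]
    failures: dict[str, str] = field(default_factory=dict)


def _pool_group(clf_name, way, condition, folds, leak) -> GroupResult:
    confs = [f.tests[condition].confusion for f in folds]
    pooled = pooled_proportion_metrics(confs)
    probs = np.concatenate([f.tests[condition].probabilities for f in folds])
    labels = np.concatenate([f.tests[condition].labels for f in folds])
    pooled.roc_auc = pooled_roc_auc(probs, labels)
    val = PooledMetrics(
        tp=sum(f.validation_successes for f in folds),
        tn=0,
        fp=sum(f.validation_trials - f.validation_successes for f in folds),
        fn=0,
        n_folds=len(folds),
    )
    return GroupResult(
        classifier=clf_name,
        way=way,
        test_condition=condition,
        pooled=pooled,
        epochs=mean_with_t4_ci([f.epoch_count for f in folds]),
        time=mean_with_t4_ci([f.training_time for f in folds]),
        validation=val,
        leakage=leak,
        fold_results=folds,
    )


def _audit_way(ds: LabeledDataset, way: str, k: int, seed: int) -> LeakageReport:
    cfg = ProtocolConfig(way=way, test_augmented=(way == "F"), k=k, seed=seed)
    tv = tt = vt = 0
    for fold in range(1, k + 1):
        rep = audit_fold(fold, *build_fold_datasets(ds, cfg, fold))
        tv += rep.parents_train_val
        tt += rep.parents_train_test
        vt += rep.parents_val_test
    return LeakageReport(tv, tt, vt)


def run_matrix(cfg: ExperimentConfig) -> ReportBundle:
    """Execute the full classifier x way matrix.

    A failure in one cell is recorded in ``bundle.failures`` (keyed by
    ``classifier/way``) and does not abort the other cells.
    """
    cards = matrix_cardinalities(len(cfg.classifiers), cfg.ways)
    ds = cfg.dataset if cfg.dataset is not None else generate_synthetic_dataset(cfg.synth)

    split_seed = derive_seed(cfg.seed, "split")
    seeds = {"master": cfg.seed, "split": split_seed}
    groups: list[GroupResult] = []
    failures: dict[str, str] = {}

    for clf_name, factory in cfg.classifiers.items():
        train_seed = derive_seed(cfg.seed, "train", clf_name)
        seeds[f"train/{clf_name}"] = train_seed
        tcfg = dataclasses.replace(cfg.training, seed=train_seed)
        for way in cfg.ways:
            cell = f"{clf_name}/{way}"
            try:
                pcfg = ProtocolConfig(way=way, test_augmented=(way == "F"),
                                      k=cfg.k, seed=split_seed)
                leak = _audit_way(ds, way, cfg.k, split_seed)
                folds = run_experiment(ds, pcfg, tcfg, factory)
                for condition in (PLAIN_TEST, AUGMENTED_TEST):
                    if condition in folds[0].tests:
                        groups.append(_pool_group(clf_name, way, condition, folds, leak))
            except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
                failures[cell] = f"{exc}\n{traceback.format_exc(limit=3)}"

    timecost: list[TimeCostResult] = []
    for clf_name in cfg.classifiers:
        rows = filter_time_cost_groups(
            [g for g in groups if g.classifier == clf_name]
        )
        if len(rows) >= 3:
            times = [g.time.mean for g in rows]
            for metric in ("accuracy", "sensitivity", "specificity"):
                vals = [getattr(g.pooled, metric).point for g in rows]
                try:
                    tc = time_cost_correlation(vals, times, metric_name=f"{clf_name}:{metric}")
                    timecost.append(tc)
                except (ValueError, ZeroDivisionError):
                    pass
            try:
                aucs = [g.pooled.roc_auc.auc for g in rows]
                timecost.append(time_cost_correlation(aucs, times,
                                                      metric_name=f"{clf_name}:roc_auc"))
            except (ValueError, ZeroDivisionError):
                pass

    return ReportBundle(groups=groups, timecost=timecost, cardinalities=cards,
                        seeds=seeds, failures=failures)


def summarize(bundle: ReportBundle) -> pd.DataFrame:
    """One row per testing group: way, test condition, metrics with CIs,
    mean epochs/times and leakage counts.

    Raises ``ValueError`` listing the missing cells if the bundle is
    incomplete (e.g. every cell failed).
    """
    expected = bundle.cardinalities["testing_groups"]
    if len(bundle.groups) != expected:
        have = {(g.classifier, g.way, g.test_condition) for g in bundle.groups}
        raise ValueError(
            f"incomplete bundle: {len(bundle.groups)}/{expected} testing groups; "
            f"failures: {sorted(bundle.failures) or 'none recorded'}; "
            f"present: {sorted(have)}"
        )
    df = pd.DataFrame([g.to_row() for g in bundle.groups])
    return df.sort_values(["classifier", "way", "test_condition"]).reset_index(drop=True)


def bundle_to_dict(bundle: ReportBundle) -> dict:
    """JSON-ready representation of every statistic in the bundle."""
    return {
        "cardinalities": bundle.cardinalities,
        "seeds": bundle.seeds,
        "failures": bundle.failures,
        "groups": summarize(bundle).to_dict(orient="records"),
        "timecost": [dataclasses.asdict(t) for t in bundle.timecost],
    }


def summary_from_dict(d: dict) -> pd.DataFrame:
    """Rebuild the summary table from a JSON representation."""
    return (pd.DataFrame(d["groups"])
            .sort_values(["classifier", "way", "test_condition"])
            .reset_index(drop=True))


def write_bundle(bundle: ReportBundle, out_dir) -> Path:
    """Write the summary CSV, machine-readable JSON, per-record test
    probabilities and the seed manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summarize(bundle).to_csv(out / "summary.csv", index=False)
    (out / "results.json").write_text(json.dumps(bundle_to_dict(bundle), indent=1))
    prob_rows = []
    for g in bundle.groups:
        for f in g.fold_results:
            ev = f.tests[g.test_condition]
            for iid, lab, prob in zip(ev.image_ids, ev.labels, ev.probabilities):
                prob_rows.append({
                    "classifier": g.classifier, "way": g.way,
                    "test_condition": g.test_condition, "fold": f.fold,
                    "image_id": iid, "true_label": int(lab),
                    "prob_positive": float(prob),
                })
    pd.DataFrame(prob_rows).to_csv(out / "test_probabilities.csv", index=False)
    (out / "seeds.json").write_text(json.dumps(bundle.seeds, indent=1))
    return out / "results.json"
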
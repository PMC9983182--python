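"""The 11 augmentation-placement protocols and their split machinery.

A *way* (A-F) fixes which data subsets are augmented and at which point
relative to the stratified k-fold test allocation and the 3:1
train/validation split:

====  ==============================================================
way   meaning
====  ==============================================================
A     make three sets, then augment validation only
B     make three sets, no augmentation
C     make three sets, then augment training only
D     make three sets, then augment training and validation separately
E     separate the test set, augment the rest, then split train/val
F     augment the whole dataset before any splitting
====  ==============================================================

Ways A-E can each be evaluated on the original or the augmented test set
(the model is unchanged); way F's test set is inherently augmented.  That
yields 6 model-building ways and 11 evaluation configurations.

Ways E and F split *after* augmentation at the individual-image level, so
members of one augmentation orbit can land in different subsets — the
information leakage this package audits and measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import derive_seed
from .augment import augment_dataset
from .dataset import LabeledDataset

__all__ = [
    "WAYS",
    "SUBSETS",
    "ProtocolConfig",
    "SplitAssignment",
    "LeakageReport",
    "StratificationError",
    "enumerate_protocols",
    "stratified_kfold",
    "split_train_val",
    "build_fold_datasets",
    "leakage_audit",
    "audit_fold",
]

WAYS = ("A", "B", "C", "D", "E", "F")
SUBSETS = ("train", "validation", "test")

_WAY_DOC = {
    "A": "make three sets, then augment validation",
    "B": "make three sets",
    "C": "make three sets, then augment training",
    "D": "make three sets, then augment both training and validation",
    "E": "separate test set, augment the rest, then make two other sets",
    "F": "augment all before making three sets",
}


class StratificationError(ValueError):
    """A class is too small (or absent) for the requested stratified split."""


@dataclass(frozen=True)
class ProtocolConfig:
    """One of the 11 evaluation configurations.

    ``test_augmented`` selects which test set the trained model is scored
    on; it does not change model building.  Way F's test set is inherently
    augmented, so ``test_augmented`` must be true there.
    """

    way: str
    test_augmented: bool = False
    k: int = 5
    seed: int = 0
    #: train:validation ratio (fixed 3:1)
    train_val_ratio: tuple[int, int] = (3, 1)

    def __post_init__(self) -> None:
        if self.way not in WAYS:
            raise ValueError(f"way must be one of {WAYS}, got {self.way!r}")
        if self.way == "F" and not self.test_augmented:
            raise ValueError("way F's test set is inherently augmented; "
                             "test_augmented must be True")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.train_val_ratio != (3, 1):
            raise ValueError("only the 3:1 train:validation ratio is supported")

    @property
    def label(self) -> str:
        return f"{self.way}{'+testaug' if self.test_augmented else ''}"

    @property
    def description(self) -> str:
        return _WAY_DOC[self.way]


def enumerate_protocols(k: int = 5, seed: int = 0) -> list[ProtocolConfig]:
    """All 11 evaluation configurations: ways A-E under both test conditions
    plus way F under its single (augmented) condition."""
    out = []
    for way in WAYS:
        for testaug in (False, True):
            if way == "F" and not testaug:
                continue
            out.append(ProtocolConfig(way=way, test_augmented=testaug, k=k, seed=seed))
    return out


def _class_groups(ds: LabeledDataset) -> dict[str, list]:
    return ds.by_class()


def stratified_kfold(ds: LabeledDataset, k: int, seed: int) -> list[list[str]]:
    """Partition a dataset into k stratified parts of image ids.

    Within each class, membership is shuffled by ``seed`` and dealt into k
    parts whose sizes differ by at most one; which parts receive the
    remainder records is itself seed-driven, so no part is systematically
    larger.  Raises :class:`StratificationError` if any class has fewer
    than k records.
    """
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(ds.class_manifest):
        recs = [r.image_id for r in ds.records if r.class_label == label]
        n = len(recs)
        if n < k:
            raise StratificationError(
                f"class {label!r} has {n} records, fewer than k={k}"
            )
        order = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[rng.permutation(k)[: n % k]] += 1
        start = 0
        for j in range(k):
            idx = order[start:start + sizes[j]]
            parts[j].extend(recs[i] for i in idx)
            start += sizes[j]
    return parts


def _train_count(n: int, rng: np.random.Generator) -> int:
    """Per-class 3:1 largest-remainder rule with a seeded coin on exact ties."""
    n_tr, n_va = (3 * n) // 4, n // 4
    leftover = n - n_tr - n_va
    if leftover:
        rem_tr = 3 * n / 4 - n_tr
        rem_va = n / 4 - n_va
        if rem_tr > rem_va or (rem_tr == rem_va and rng.random() < 0.5):
            n_tr += leftover
    return n_tr


def split_train_val(ds: LabeledDataset, seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffle and split 3:1 into train and validation, stratified per class.

    Each class is split independently: the training part receives
    ``floor(3n/4)`` records plus the leftover record when the training-side
    remainder dominates (seeded coin on the exact tie at ``n ≡ 2 mod 4``).
    Raises :class:`StratificationError` on single-class input.
    """
    if len(ds) == 0 or len(ds.class_manifest) < 2:
        raise StratificationError("train/validation split needs both classes present")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for label in sorted(ds.class_manifest):
        recs = [r.image_id for r in ds.records if r.class_label == label]
        order = rng.permutation(len(recs))
        n_tr = _train_count(len(recs), rng)
        train_ids.extend(recs[i] for i in order[:n_tr])
        val_ids.extend(recs[i] for i in order[n_tr:])
    return ds.subset(train_ids), ds.subset(val_ids)


@dataclass
class SplitAssignment:
    """Per-fold mapping of image ids to the three subsets."""

    fold_index: int
    subset_of: dict[str, str] = field(default_factory=dict)

    def ids_in(self, subset: str) -> list[str]:
        return [i for i, s in self.subset_of.items() if s == subset]


@dataclass(frozen=True)
class LeakageReport:
    """Counts of parents whose augmentation orbit spans two subsets."""

    parents_train_val: int
    parents_train_test: int
    parents_val_test: int

    @property
    def total(self) -> int:
        return self.parents_train_val + self.parents_train_test + self.parents_val_test


def build_fold_datasets(
    ds: LabeledDataset, cfg: ProtocolConfig, fold: int
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Construct the (train, validation, test) datasets of one fold.

    ``ds`` must contain only originals; ``fold`` is 1-based.  Ways A-D
    split the originals first (k-fold test allocation, then 3:1 train/val)
    and augment the named subsets in place; way E augments the non-test
    originals before the 3:1 split; way F augments everything before any
    splitting.  For ways A-E the test part is augmented after allocation
    when ``cfg.test_augmented``.
    """
    if ds.provenance_flag:
        raise ValueError("build_fold_datasets expects a dataset of originals")
    if not 1 <= fold <= cfg.k:
        raise ValueError(f"fold must be in 1..{cfg.k}, got {fold}")

    kfold_seed = derive_seed(cfg.seed, "kfold")
    tv_seed = derive_seed(cfg.seed, "trainval", fold)

    if cfg.way == "F":
        pool = augment_dataset(ds)
        parts = stratified_kfold(pool, cfg.k, kfold_seed)
        test = pool.subset(parts[fold - 1])
        rest = pool.subset(set(i.image_id for i in pool) - set(parts[fold - 1]))
        train, val = split_train_val(rest, tv_seed)
        return train, val, test

    parts = stratified_kfold(ds, cfg.k, kfold_seed)
    test = ds.subset(parts[fold - 1])
    rest = ds.subset(set(r.image_id for r in ds) - set(parts[fold - 1]))

    if cfg.way == "E":
        train, val = split_train_val(augment_dataset(rest), tv_seed)
    else:
        train, val = split_train_val(rest, tv_seed)
        if cfg.way in ("C", "D"):
            train = augment_dataset(train)
        if cfg.way in ("A", "D"):
            val = augment_dataset(val)

    if cfg.test_augmented:
        test = augment_dataset(test)
    return train, val, test


def assignment_from_parts(
    fold: int, train: LabeledDataset, val: LabeledDataset, test: LabeledDataset
) -> SplitAssignment:
    sub: dict[str, str] = {}
    for name, part in zip(SUBSETS, (train, val, test)):
        for r in part:
            if r.image_id in sub:
                raise ValueError(f"record {r.image_id!r} assigned to two subsets")
            sub[r.image_id] = name
    return SplitAssignment(fold_index=fold, subset_of=sub)


def leakage_audit(assignment: SplitAssignment, ds: LabeledDataset) -> LeakageReport:
    """Count parents whose orbit members occupy more than one subset.

    ``ds`` must contain every assigned record (it supplies the parent of
    each image id).
    """
    parent_of = ds.parent_of()
    seen: dict[str, set[str]] = {}
    for image_id, subset in assignment.subset_of.items():
        if image_id not in parent_of:
            raise KeyError(f"record {image_id!r} not present in the provenance dataset")
        seen.setdefault(parent_of[image_id], set()).add(subset)
    def pair(a: str, b: str) -> int:
        return sum(1 for subs in seen.values() if a in subs and b in subs)
    return LeakageReport(
        parents_train_val=pair("train", "validation"),
        parents_train_test=pair("train", "test"),
        parents_val_test=pair("validation", "test"),
    )


def audit_fold(
    fold: int, train: LabeledDataset, val: LabeledDataset, test: LabeledDataset
) -> LeakageReport:
    """Leakage audit straight from the three constructed fold datasets."""
    union = LabeledDataset(train.records + val.records + test.records)
    return leakage_audit(assignment_from_parts(fold, train, val, test), union)
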
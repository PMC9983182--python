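"""Protocol enumeration, stratified splitting, fold construction, leakage."""

from collections import Counter

import numpy as np
import pytest

from augsplit.augment import augment_dataset
from augsplit.dataset import NEGATIVE_LABEL, POSITIVE_LABEL, LabeledDataset
from augsplit.protocols import (
    WAYS,
    ProtocolConfig,
    StratificationError,
    audit_fold,
    build_fold_datasets,
    enumerate_protocols,
    split_train_val,
    stratified_kfold,
)

from conftest import make_dataset


def _mixed_dataset(n_pos, n_neg, seed=0):
    ds = make_dataset(max(n_pos, n_neg), seed=seed)
    keep = ([r.image_id for r in ds if r.class_label == POSITIVE_LABEL][:n_pos]
            + [r.image_id for r in ds if r.class_label == NEGATIVE_LABEL][:n_neg])
    return ds.subset(keep)


# --- enumeration ------------------------------------------------------------

def test_enumeration_cardinalities():
    protos = enumerate_protocols()
    assert len(protos) == 11
    assert len({p.way for p in protos}) == 6
    both = Counter(p.way for p in protos)
    assert sorted(w for w, n in both.items() if n == 2) == ["A", "B", "C", "D", "E"]
    assert both["F"] == 1
    f = next(p for p in protos if p.way == "F")
    assert f.test_augmented


def test_way_f_with_plain_test_rejected():
    with pytest.raises(ValueError, match="inherently augmented"):
        ProtocolConfig(way="F", test_augmented=False)


# --- stratified k-fold ------------------------------------------------------

def test_kfold_divisible_case_exact():
    ds = make_dataset(50)
    parts = stratified_kfold(ds, 5, seed=1)
    for part in parts:
        labels = Counter(r.class_label for r in ds.subset(part))
        assert labels[POSITIVE_LABEL] == 10 and labels[NEGATIVE_LABEL] == 10


def test_kfold_remainder_spreading():
    """52 positives over 5 folds must give part sizes {11, 11, 10, 10, 10}."""
    ds = _mixed_dataset(52, 50)
    parts = stratified_kfold(ds, 5, seed=3)
    pos_sizes = sorted(
        sum(1 for r in ds.subset(p) if r.class_label == POSITIVE_LABEL) for p in parts
    )
    assert pos_sizes == [10, 10, 10, 11, 11]
    neg_sizes = [sum(1 for r in ds.subset(p) if r.class_label == NEGATIVE_LABEL)
                 for p in parts]
    assert sorted(neg_sizes) == [10, 10, 10, 10, 10]


def test_kfold_parts_partition_dataset():
    ds = _mixed_dataset(13, 17)
    parts = stratified_kfold(ds, 4, seed=9)
    ids = [i for p in parts for i in p]
    assert sorted(ids) == sorted(r.image_id for r in ds)


def test_kfold_class_smaller_than_k_rejected():
    ds = _mixed_dataset(4, 10)
    with pytest.raises(StratificationError, match="fewer than k"):
        stratified_kfold(ds, 5, seed=0)


# --- 3:1 train/validation split --------------------------------------------

def test_split_divisible_case():
    ds = make_dataset(40)
    train, val = split_train_val(ds, seed=2)
    assert len(train) == 60 and len(val) == 20
    assert Counter(train.labels) == {POSITIVE_LABEL: 30, NEGATIVE_LABEL: 30}
    assert Counter(val.labels) == {POSITIVE_LABEL: 10, NEGATIVE_LABEL: 10}


def test_split_rounding_rule_five_pos_three_neg():
    """Largest-remainder per class: 5 -> 4/1 (remainder .75 vs .25);
    3 -> 2/1 (remainder .25 vs .75 goes to validation)."""
    ds = _mixed_dataset(5, 3)
    train, val = split_train_val(ds, seed=0)
    assert Counter(train.labels) == {POSITIVE_LABEL: 4, NEGATIVE_LABEL: 2}
    assert Counter(val.labels) == {POSITIVE_LABEL: 1, NEGATIVE_LABEL: 1}
    assert sorted([r.image_id for r in train] + [r.image_id for r in val]) \
        == sorted(r.image_id for r in ds)


def test_split_seed_changes_membership_not_sizes():
    ds = make_dataset(40)
    t1, v1 = split_train_val(ds, seed=1)
    t2, v2 = split_train_val(ds, seed=2)
    assert len(t1) == len(t2) and len(v1) == len(v2)
    assert {r.image_id for r in t1} != {r.image_id for r in t2}


def test_split_single_class_rejected():
    ds = _mixed_dataset(8, 0)
    with pytest.raises(StratificationError, match="both classes"):
        split_train_val(ds, seed=0)


# --- fold construction ------------------------------------------------------

def test_way_b_sizes_and_no_derivatives():
    ds = make_dataset(100)  # 200 originals
    cfg = ProtocolConfig(way="B", k=5, seed=4)
    train, val, test = build_fold_datasets(ds, cfg, 1)
    assert (len(train), len(val), len(test)) == (120, 40, 40)
    for part in (train, val, test):
        assert not part.provenance_flag


def test_way_e_sizes():
    ds = make_dataset(100)
    cfg = ProtocolConfig(way="E", k=5, seed=4)
    train, val, test = build_fold_datasets(ds, cfg, 1)
    assert len(test) == 40 and not test.provenance_flag
    assert len(train) + len(val) == 8 * 160
    assert len(train) == 960 and len(val) == 320


def test_way_f_sizes_and_split_level():
    ds = make_dataset(100)
    cfg = ProtocolConfig(way="F", test_augmented=True, k=5, seed=4)
    train, val, test = build_fold_datasets(ds, cfg, 1)
    assert len(train) + len(val) + len(test) == 1600
    assert (len(train), len(val), len(test)) == (960, 320, 320)
    # orbit members may land in different subsets
    rep = audit_fold(1, train, val, test)
    assert rep.total > 0


@pytest.mark.parametrize("way", WAYS)
def test_partition_property_every_way(way):
    ds = make_dataset(30)
    cfg = ProtocolConfig(way=way, test_augmented=(way == "F"), k=5, seed=7)
    train, val, test = build_fold_datasets(ds, cfg, 2)
    ids = [r.image_id for part in (train, val, test) for r in part]
    assert len(ids) == len(set(ids))  # disjoint
    if way == "B":
        assert len(ids) == len(ds)
    elif way == "F":
        assert len(ids) == 8 * len(ds)


@pytest.mark.parametrize("way", WAYS)
def test_cross_fold_test_disjointness(way):
    ds = make_dataset(25)
    cfg = ProtocolConfig(way=way, test_augmented=(way == "F"), k=5, seed=5)
    seen: set[str] = set()
    total = 0
    for fold in range(1, 6):
        _, _, test = build_fold_datasets(ds, cfg, fold)
        ids = {r.image_id for r in test}
        assert not (seen & ids)
        seen |= ids
        total += len(ids)
    expected_pool = 8 * len(ds) if way == "F" else len(ds)
    if way in ("A", "B", "C", "D", "E") and cfg.test_augmented:
        expected_pool = None
    if way == "F":
        assert total == expected_pool
    elif not cfg.test_augmented:
        assert total == len(ds)


def test_stratification_of_subsets():
    ds = make_dataset(50)
    cfg = ProtocolConfig(way="E", k=5, seed=8)
    train, val, test = build_fold_datasets(ds, cfg, 3)
    for part in (train, val, test):
        counts = Counter(part.labels)
        assert abs(counts[POSITIVE_LABEL] - counts[NEGATIVE_LABEL]) <= 2


def test_bad_fold_index_rejected(tiny_ds):
    cfg = ProtocolConfig(way="B", k=5, seed=0)
    with pytest.raises(ValueError, match="fold"):
        build_fold_datasets(tiny_ds, cfg, 6)


def test_pre_augmented_input_rejected(tiny_ds):
    cfg = ProtocolConfig(way="B", k=5, seed=0)
    with pytest.raises(ValueError, match="originals"):
        build_fold_datasets(augment_dataset(tiny_ds), cfg, 1)


# --- leakage audit ----------------------------------------------------------

@pytest.mark.parametrize("way,expect", [
    ("A", "none"), ("B", "none"), ("C", "none"), ("D", "none"),
    ("E", "train_val_only"), ("F", "cross_test"),
])
def test_structural_leakage_pattern(way, expect):
    ds = make_dataset(50, seed=2)
    cfg = ProtocolConfig(way=way, test_augmented=(way == "F"), k=5, seed=21)
    for fold in (1, 3):
        rep = audit_fold(fold, *build_fold_datasets(ds, cfg, fold))
        if expect == "none":
            assert rep.total == 0
        elif expect == "train_val_only":
            assert rep.parents_train_val > 0
            assert rep.parents_train_test == 0
            assert rep.parents_val_test == 0
        else:
            assert rep.parents_train_test > 0


def test_leakage_with_augmented_test_still_zero_for_abcd():
    ds = make_dataset(30, seed=3)
    for way in "ABCD":
        cfg = ProtocolConfig(way=way, test_augmented=True, k=5, seed=1)
        rep = audit_fold(1, *build_fold_datasets(ds, cfg, 1))
        assert rep.total == 0
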
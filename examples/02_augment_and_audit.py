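"""Eight-fold dihedral augmentation and the leakage audit.

Builds the train/validation/test datasets of one cross-validation fold for
two contrasting placements — way B (no augmentation) and way F (augment the
whole dataset before any splitting) — and counts parents whose augmentation
orbit spans two subsets.  Way F should leak across every subset pair; the
split-first ways should audit to zero.
"""

from augsplit import (
    ProtocolConfig,
    SynthParams,
    augment_dataset,
    audit_fold,
    build_fold_datasets,
    generate_synthetic_dataset,
)

ds = generate_synthetic_dataset(SynthParams(n_per_class=100, seed=1))
aug = augment_dataset(ds)
print(f"{len(ds)} originals -> {len(aug)} records "
      f"({len(aug) // len(ds)}-fold, full dihedral orbits)")

for way in ("B", "E", "F"):
    cfg = ProtocolConfig(way=way, test_augmented=(way == "F"), k=5, seed=11)
    train, val, test = build_fold_datasets(ds, cfg, fold=1)
    rep = audit_fold(1, train, val, test)
    print(f"way {way}: sizes {len(train)}/{len(val)}/{len(test)}; "
          f"leaking parents train-val={rep.parents_train_val} "
          f"train-test={rep.parents_train_test} val-test={rep.parents_val_test}")
# Ways that split originals first (A-D) keep whole orbits inside one subset;
# way E mixes orbits between train and validation only; way F can leak into
# the test set itself, which is what inflates its test metrics.
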
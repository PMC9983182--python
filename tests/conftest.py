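import numpy as np
import pytest

from augsplit.dataset import (
    IDENTITY,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    ImageRecord,
    LabeledDataset,
)


def make_dataset(n_per_class: int, side: int = 8, seed: int = 0) -> LabeledDataset:
    """A tiny deterministic two-class dataset of pure-noise originals."""
    rng = np.random.default_rng(seed)
    records = []
    for label in (NEGATIVE_LABEL, POSITIVE_LABEL):
        for i in range(n_per_class):
            iid = f"{label}_{i:04d}"
            records.append(
                ImageRecord(iid, iid, IDENTITY, label, rng.random((side, side)))
            )
    return LabeledDataset(records)


@pytest.fixture
def tiny_ds() -> LabeledDataset:
    return make_dataset(10)


class StubClassifier:
    """Scripted classifier: validation accuracy follows a preset schedule.

    ``schedule(epoch)`` returns the fraction of validation records (in
    dataset order) to predict correctly after that epoch; the stub stores
    the validation labels it is given at construction.
    """

    def __init__(self, val_labels, schedule):
        self.val_labels = np.asarray(val_labels)
        self.schedule = schedule
        self.epoch = 0

    def train_epoch(self, X, y, order, cfg) -> None:
        self.epoch += 1

    def predict_proba(self, X) -> np.ndarray:
        n = X.shape[0]
        if n != len(self.val_labels):  # test-set call: predict all positive
            return np.full(n, 0.9)
        frac = self.schedule(self.epoch)
        k = int(round(frac * n))
        p = np.where(self.val_labels == 1, 0.1, 0.9).astype(float)  # all wrong
        p[:k] = np.where(self.val_labels[:k] == 1, 0.9, 0.1)        # first k right
        return p

    def get_state(self):
        return {"epoch": self.epoch}

    def set_state(self, state):
        self.restored_epoch = state["epoch"]
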
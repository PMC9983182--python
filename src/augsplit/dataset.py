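"""Core containers: labeled image records with augmentation provenance.

Every image in a study is an :class:`ImageRecord`.  Originals are their own
parent; augmentation derivatives remember the parent image and the dihedral
transform that produced them, which is what makes information leakage between
data subsets auditable after the fact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "IDENTITY",
    "ImageRecord",
    "LabeledDataset",
    "DatasetError",
]

#: Positive class: the malignancy analog (urothelial-carcinoma stand-in).
POSITIVE_LABEL = "carcinoma"
#: Negative class: the benign analog (inflammation stand-in).
NEGATIVE_LABEL = "inflammation"

#: Code of the identity dihedral element (originals carry this tag).
IDENTITY = "e"


class DatasetError(ValueError):
    """A dataset violates one of its structural invariants."""


@dataclass
class ImageRecord:
    """One image plus its label and augmentation provenance.

    ``transform_id == "e"`` if and only if the record is an original, in which
    case ``image_id == parent_id``.
    """

    image_id: str
    parent_id: str
    transform_id: str
    class_label: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if (self.transform_id == IDENTITY) != (self.image_id == self.parent_id):
            raise DatasetError(
                f"record {self.image_id!r}: identity transform and "
                f"image_id == parent_id must coincide"
            )

    @property
    def is_original(self) -> bool:
        return self.transform_id == IDENTITY


@dataclass
class LabeledDataset:
    """An ordered collection of :class:`ImageRecord` with unique ids."""

    records: list[ImageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise DatasetError(f"duplicate image_id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_manifest(self) -> dict[str, int]:
        """Per-class record counts."""
        return dict(Counter(r.class_label for r in self.records))

    @property
    def provenance_flag(self) -> bool:
        """True if any record is an augmentation derivative."""
        return any(not r.is_original for r in self.records)

    @property
    def labels(self) -> list[str]:
        return [r.class_label for r in self.records]

    def subset(self, image_ids) -> "LabeledDataset":
        wanted = set(image_ids)
        return LabeledDataset([r for r in self.records if r.image_id in wanted])

    def by_class(self) -> dict[str, list[ImageRecord]]:
        out: dict[str, list[ImageRecord]] = {}
        for r in self.records:
            out.setdefault(r.class_label, []).append(r)
        return out

    def parent_of(self) -> dict[str, str]:
        """image_id -> parent_id lookup."""
        return {r.image_id: r.parent_id for r in self.records}


def stack_pixels(ds: LabeledDataset, dtype=np.float32) -> np.ndarray:
    """Stack a dataset's images into an ``(n, side, side)`` array."""
    return np.stack([r.pixels for r in ds.records]).astype(dtype, copy=False)


def label_vector(ds: LabeledDataset) -> np.ndarray:
    """Binary label vector: 1 for the positive (carcinoma-analog) class."""
    return np.fromiter(
        (1 if r.class_label == POSITIVE_LABEL else 0 for r in ds.records),
        dtype=np.int64,
        count=len(ds),
    )
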
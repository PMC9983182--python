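"""Eight-fold dihedral augmentation with provenance, plus dataset I/O.

The augmentation group is the dihedral group of order 8 acting on square
images: the four rotations by multiples of 90° and their horizontal flips.
All transforms are lossless pixel permutations (no interpolation), so
augmenting never alters the class-relevant content of an image — only its
orientation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .dataset import (
    IDENTITY,
    DatasetError,
    ImageRecord,
    LabeledDataset,
)
from .synthdata import MANIFEST_COLUMNS, MANIFEST_NAME

__all__ = [
    "DIHEDRAL_CODES",
    "apply_transform",
    "compose",
    "inverse",
    "augment_dataset",
    "augment_records",
    "read_dataset",
    "resize_dataset",
    "derivative_id",
]

#: The 8 dihedral elements: ``e`` identity, ``rXX`` counter-clockwise
#: rotations, and ``f*`` the horizontal flip of each rotation (flip applied
#: after the rotation).
DIHEDRAL_CODES = ("e", "r90", "r180", "r270", "f", "fr90", "fr180", "fr270")

# code -> (flip applied after rotation, quarter-turns CCW)
_DECODE = {
    "e": (False, 0), "r90": (False, 1), "r180": (False, 2), "r270": (False, 3),
    "f": (True, 0), "fr90": (True, 1), "fr180": (True, 2), "fr270": (True, 3),
}
_ENCODE = {v: k for k, v in _DECODE.items()}


def apply_transform(pixels: np.ndarray, t: str) -> np.ndarray:
    """Apply dihedral element ``t`` to a square image.

    Rotations are counter-clockwise; ``f`` is a horizontal (left-right)
    flip applied after the rotation.  The identity returns the input
    array itself.
    """
    if t not in _DECODE:
        raise ValueError(f"unknown dihedral code {t!r}")
    a = np.asarray(pixels)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square 2-d array, got shape {a.shape}")
    flip, k = _DECODE[t]
    if not flip and k == 0:
        return a
    out = np.rot90(a, k) if k else a
    if flip:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def compose(first: str, then: str) -> str:
    """The single element equal to applying ``first`` and then ``then``.

    Uses the relation ``R^k F = F R^(-k)`` for CCW quarter-turn ``R`` and
    left-right flip ``F`` (actions written left-to-right in application
    order, i.e. the composite action is ``then ∘ first``).
    """
    f1, k1 = _DECODE[first]
    f2, k2 = _DECODE[then]
    # action(first) = F^f1 R^k1 (R applied first). Composite = F^f2 R^k2 F^f1 R^k1.
    if f1:
        # R^k2 F = F R^(-k2)
        return _ENCODE[(not f2, (k1 - k2) % 4)]
    return _ENCODE[(f2, (k1 + k2) % 4)]


def inverse(t: str) -> str:
    """The dihedral element undoing ``t``."""
    f, k = _DECODE[t]
    return _ENCODE[(f, k if f else (-k) % 4)]


def derivative_id(parent_id: str, t: str) -> str:
    return parent_id if t == IDENTITY else f"{parent_id}:{t}"


def augment_records(records) -> list[ImageRecord]:
    """Expand originals into full 8-element dihedral orbits."""
    out: list[ImageRecord] = []
    for r in records:
        for t in DIHEDRAL_CODES:
            if t == IDENTITY:
                out.append(r)
            else:
                out.append(
                    ImageRecord(
                        image_id=derivative_id(r.parent_id, t),
                        parent_id=r.parent_id,
                        transform_id=t,
                        class_label=r.class_label,
                        pixels=apply_transform(r.pixels, t),
                    )
                )
    return out


def augment_dataset(ds: LabeledDataset) -> LabeledDataset:
    """Eight-fold augmentation of a dataset of originals.

    Each original yields its full orbit: itself (tagged with the identity
    element) plus 7 derivatives carrying the parent id and their transform
    code.  Labels are inherited.  Datasets that already contain derivatives
    are rejected, preventing accidental 64-fold inflation.
    """
    if ds.provenance_flag:
        raise DatasetError("dataset already contains augmentation derivatives")
    return LabeledDataset(augment_records(ds.records))


def _load_png(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def read_dataset(root, manifest=None) -> LabeledDataset:
    """Read a folder-per-class image dataset, optionally via a manifest CSV.

    With a manifest (explicit path, or ``<root>/manifest.csv`` if present),
    ids, parents, transforms and labels come from its columns.  Without one,
    every PNG/JPEG under ``<root>/<class>/`` becomes an original labeled by
    its folder name; exactly two class folders are required.
    """
    root = Path(root)
    if manifest is None and (root / MANIFEST_NAME).is_file():
        manifest = root / MANIFEST_NAME
    if manifest is not None:
        df = pd.read_csv(manifest, dtype=str)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"manifest lacks columns {missing}")
        records = []
        for row in df.itertuples(index=False):
            path = root / row.path
            if not path.is_file():
                raise FileNotFoundError(f"manifest references missing file {path}")
            records.append(
                ImageRecord(
                    image_id=row.image_id,
                    parent_id=row.parent_id,
                    transform_id=row.transform_id,
                    class_label=row.class_label,
                    pixels=_load_png(path),
                )
            )
        return LabeledDataset(records)

    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) != 2:
        raise DatasetError(
            f"expected exactly 2 class folders under {root}, found {len(class_dirs)}"
        )
    records = []
    for d in class_dirs:
        for path in sorted(d.iterdir()):
            if path.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            image_id = path.stem
            records.append(
                ImageRecord(
                    image_id=image_id,
                    parent_id=image_id,
                    transform_id=IDENTITY,
                    class_label=d.name,
                    pixels=_load_png(path),
                )
            )
    if not records:
        raise DatasetError(f"no images found under {root}")
    return LabeledDataset(records)


def resize_dataset(ds: LabeledDataset, side: int) -> LabeledDataset:
    """Rescale every image to ``side x side`` (bilinear, antialiased).

    Metadata is unchanged; resizing to an image's own size is a no-op.  The
    interpolation kernel is symmetric, so resizing commutes with the
    dihedral transforms on square inputs.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    out = []
    for r in ds.records:
        if r.pixels.shape == (side, side):
            px = r.pixels
        else:
            px = _sk_resize(
                r.pixels, (side, side), order=1, anti_aliasing=r.pixels.shape[0] > side,
                mode="reflect", preserve_range=True,
            )
            px = np.clip(px, 0.0, 1.0)
        out.append(
            ImageRecord(
                image_id=r.image_id,
                parent_id=r.parent_id,
                transform_id=r.transform_id,
                class_label=r.class_label,
                pixels=px,
            )
        )
    return LabeledDataset(out)
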
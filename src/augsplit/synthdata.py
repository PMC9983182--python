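"""Synthetic two-class image generator for augmentation-placement studies.

The generator emulates the statistical structure that makes augmentation
placement an interesting question for histopathology patches, using
parametric textures instead of photographs:

* **Class signal** — two exactly orientation-invariant components: a
  zero-mean isotropic Gaussian texture whose spatial correlation length
  depends on the class (the benign analog is smoother, the malignant
  analog rougher), and a class-dependent radial ring template (a function
  of the distance from the image center, which every rotation and flip of
  the pixel grid preserves).  The template gives a small first-order cue a
  classifier can pick up from few examples; the texture carries the
  second-order bulk of the signal.  Mirroring the orientation invariance
  of a histological diagnosis, neither component changes its
  class-conditional law under any of the 8 dihedral transforms.
* **Fingerprint** — each image carries a unique, dihedral-*symmetric*
  texture field.  Every member of an image's augmentation orbit therefore
  shares the identical fingerprint, which is what makes derivatives of one
  parent mutually predictive and information leakage measurable.
* **Nuisance anisotropy** — a label-independent oriented texture (shared by
  both classes) emulating the orientation-dependent nuisance structure of
  real photographs (illumination gradients, scanning direction, sectioning
  artefacts).  It carries no class information, but a model trained only on
  originals adapts to its orientation statistics and degrades on transformed
  inputs — the mechanism behind the study's test-set-augmentation findings.
* **Pixel noise** — iid Gaussian noise in intensity units.

Pixel intensities live in ``[0, 1]`` and are clamped after composition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from ._rng import derive_rng
from .dataset import (
    IDENTITY,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    DatasetError,
    ImageRecord,
    LabeledDataset,
)

__all__ = [
    "SynthParams",
    "SynthParamsError",
    "generate_synthetic_dataset",
    "write_dataset",
    "MANIFEST_NAME",
    "MANIFEST_COLUMNS",
]

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = ["image_id", "parent_id", "transform_id", "class_label", "path"]

#: Overall amplitude mapping unit-variance texture onto the [0, 1] intensity scale.
_AMPLITUDE = 0.12
#: Correlation lengths (pixels) of the class textures; the positive
#: (carcinoma-analog) class is the rougher one.
_SIGMA_NEG = 1.8
_SIGMA_POS = 0.9
#: Smoothing scales of the oriented nuisance texture (rows, columns): smooth
#: horizontal banding, emulating illumination/scanning-direction artefacts.
_SIGMA_NUISANCE = (1.2, 8.0)
#: Smoothing scale of the fingerprint field before symmetrization.
_SIGMA_FINGERPRINT = 1.0
#: Radial class template: ring period in pixels and its amplitude relative
#: to class_signal_strength.
_RING_PERIOD = 8.0
_TEMPLATE_RATIO = 0.25


class SynthParamsError(ValueError):
    """Invalid synthetic-data parameters; the message names the field."""


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic dataset.

    Parameters
    ----------
    n_per_class
        Number of original images per class.
    image_size
        Pixels per side (square images).
    class_signal_strength
        Amplitude of the class-discriminative isotropic texture, relative to
        the fingerprint/nuisance scale.  Zero removes all class information.
    fingerprint_strength
        Amplitude of the per-image dihedral-symmetric identity texture.
    noise_sd
        Standard deviation of iid pixel noise, in intensity units.
    nuisance_anisotropy
        Amplitude of the label-independent oriented nuisance texture.
    seed
        Master seed; identical parameters and seed give bit-identical output.
    """

    n_per_class: int = 100
    image_size: int = 32
    class_signal_strength: float = 1.0
    fingerprint_strength: float = 1.2
    noise_sd: float = 0.02
    nuisance_anisotropy: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise SynthParamsError("n_per_class must be >= 1")
        if self.image_size < 8:
            raise SynthParamsError("image_size must be >= 8")
        for name in ("class_signal_strength", "fingerprint_strength",
                     "noise_sd", "nuisance_anisotropy"):
            if getattr(self, name) < 0:
                raise SynthParamsError(f"{name} must be >= 0")

    def replace(self, **kw) -> "SynthParams":
        return dataclasses.replace(self, **kw)


def _unit_field(rng: np.random.Generator, side: int, sigma) -> np.ndarray:
    """Smoothed periodic Gaussian field, normalized to unit variance."""
    f = gaussian_filter(rng.standard_normal((side, side)), sigma, mode="wrap")
    return f / f.std()


def _radial_template(side: int) -> np.ndarray:
    """Unit-variance cosine ring pattern in the distance from the center.

    Exactly invariant under all 8 dihedral transforms of the pixel grid.
    """
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    ring = np.cos(2.0 * np.pi * r / _RING_PERIOD)
    return ring / ring.std()


def _symmetrize(field: np.ndarray) -> np.ndarray:
    """Average a field over the 8 dihedral transforms (making it invariant)."""
    acc = np.zeros_like(field)
    for k in range(4):
        r = np.rot90(field, k)
        acc += r
        acc += np.fliplr(r)
    acc /= 8.0
    return acc


def _compose_image(rng: np.random.Generator, p: SynthParams, positive: bool) -> np.ndarray:
    side = p.image_size
    sigma_class = _SIGMA_POS if positive else _SIGMA_NEG
    texture = _unit_field(rng, side, sigma_class)
    template = (1.0 if positive else -1.0) * _TEMPLATE_RATIO * _radial_template(side)
    fingerprint = _symmetrize(_unit_field(rng, side, _SIGMA_FINGERPRINT))
    fingerprint /= max(fingerprint.std(), 1e-12)
    nuisance = _unit_field(rng, side, _SIGMA_NUISANCE)
    img = 0.5 + _AMPLITUDE * (
        p.class_signal_strength * (texture + template)
        + p.fingerprint_strength * fingerprint
        + p.nuisance_anisotropy * nuisance
    )
    img = img + p.noise_sd * rng.standard_normal((side, side))
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_dataset(params: SynthParams) -> LabeledDataset:
    """Generate ``2 * n_per_class`` original images, ``n_per_class`` per class.

    Each image is drawn independently from a per-image generator keyed by
    ``(seed, class, index)``, so the pixels of image *i* do not depend on how
    many other images are requested.
    """
    records: list[ImageRecord] = []
    for label, positive in ((NEGATIVE_LABEL, False), (POSITIVE_LABEL, True)):
        for i in range(params.n_per_class):
            rng = derive_rng(params.seed, "image", label, i)
            image_id = f"{label}_{i:05d}"
            records.append(
                ImageRecord(
                    image_id=image_id,
                    parent_id=image_id,
                    transform_id=IDENTITY,
                    class_label=label,
                    pixels=_compose_image(rng, params, positive),
                )
            )
    return LabeledDataset(records)


def _encode_u8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8)


def write_dataset(ds: LabeledDataset, root) -> Path:
    """Write a dataset as folder-per-class 8-bit grayscale PNGs plus a manifest.

    Layout: ``<root>/<class_label>/<image_id>.png``; the manifest CSV at
    ``<root>/manifest.csv`` has columns ``image_id, parent_id, transform_id,
    class_label, path`` (paths relative to ``root``).  Returns the manifest
    path.
    """
    if len(ds) == 0:
        raise DatasetError("refusing to write an empty dataset")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in ds.records:
        fname = r.image_id.replace(":", "__") + ".png"
        rel = Path(r.class_label) / fname
        (root / r.class_label).mkdir(exist_ok=True)
        Image.fromarray(_encode_u8(r.pixels), mode="L").save(root / rel)
        rows.append(
            {
                "image_id": r.image_id,
                "parent_id": r.parent_id,
                "transform_id": r.transform_id,
                "class_label": r.class_label,
                "path": str(rel),
            }
        )
    manifest = root / MANIFEST_NAME
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
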
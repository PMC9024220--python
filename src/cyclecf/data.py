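"""Loading two-class image directories and stratified corpus splitting.

The expected directory layout is ``root/<class_a>/*.png`` and
``root/<class_b>/*.png`` with exactly two class subfolders.  For the chest
x-ray use case this package targets, the directory would contain the
"Normal" and "Lung Opacity" images of the RSNA Pneumonia Detection
Challenge after keeping only those two classes and removing duplicate
patients (14,863 images: 8,851 normal, 6,012 opacity); preparing that
directory from the DICOM release is outside this package's scope.

Intensities are mapped to [0, 1] at this I/O boundary; downstream modules
convert to their own ranges (classifier [0, 1], generators [-1, 1])
explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import LayoutError, ParameterError, SizeError
from .images import Label, LabeledImage

__all__ = ["CorpusPartitions", "load_image_directory", "split_corpus",
           "write_manifest"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass(frozen=True)
class CorpusPartitions:
    """A stratified train/validation/test partition of a labeled corpus."""

    train: list[LabeledImage]
    validation: list[LabeledImage]
    test: list[LabeledImage]
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self):
        ids = [im.id for part in (self.train, self.validation, self.test)
               for im in part]
        if len(ids) != len(set(ids)):
            raise ParameterError("partitions share image ids")

    @property
    def all_images(self) -> list[LabeledImage]:
        return [*self.train, *self.validation, *self.test]

    def by_label(self, part: str, label: Label) -> list[LabeledImage]:
        return [im for im in getattr(self, part) if im.label is label]


def _load_one(path: Path, image_size: int) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float32)
    except Exception as exc:  # noqa: BLE001 - re-raise naming the file
        raise IOError(f"cannot read image file {path}") from exc
    if arr.ndim == 3:                     # RGB(A) -> plain channel average
        arr = arr[..., :3].mean(axis=2)
    arr = arr / 255.0
    if arr.shape != (image_size, image_size):
        im = Image.fromarray(arr.astype(np.float32), mode="F")
        im = im.resize((image_size, image_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32)
    return np.clip(arr, 0.0, 1.0)


def load_image_directory(path: str | Path, image_size: int,
                         class_names: tuple[str, str] | None = None
                         ) -> list[LabeledImage]:
    """Load a two-class image directory into labeled images.

    ``class_names`` fixes which subfolder maps to class X (first element)
    and class Y (second); by default the alphabetically first subfolder is
    class X.  Images are converted to a single channel (RGB by channel
    average), bilinearly resized to ``image_size``, and scaled to [0, 1].
    Ids are ``<folder>/<filename-stem>``, stable across reloads.
    """
    root = Path(path)
    if not root.is_dir():
        raise LayoutError(f"{root} is not a directory")
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(subdirs) != 2:
        raise LayoutError(
            f"{root} must contain exactly two class subfolders, "
            f"found {[d.name for d in subdirs]}")
    if class_names is not None:
        wanted = {d.name: d for d in subdirs}
        if set(class_names) != set(wanted):
            raise LayoutError(
                f"class_names {class_names} do not match subfolders "
                f"{sorted(wanted)}")
        subdirs = [wanted[class_names[0]], wanted[class_names[1]]]
    corpus: list[LabeledImage] = []
    for sub, label in zip(subdirs, (Label.CLASS_X, Label.CLASS_Y)):
        files = sorted(p for p in sub.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise LayoutError(f"class folder {sub} contains no images")
        for f in files:
            corpus.append(LabeledImage(pixels=_load_one(f, image_size),
                                       label=label, id=f"{sub.name}/{f.stem}"))
    return corpus


def split_corpus(corpus: list[LabeledImage],
                 fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                 seed: int = 0) -> CorpusPartitions:
    """Label-stratified random train/validation/test split.

    Within each class the images are shuffled by ``seed``; validation and
    test receive ``floor(fraction * n)`` images and the remainder goes to
    train, so per-class proportions deviate from the request by at most one
    image.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ParameterError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[LabeledImage]] = {"train": [], "validation": [], "test": []}
    for label in Label:
        group = sorted((im for im in corpus if im.label is label),
                       key=lambda im: im.id)
        if not group:
            continue
        if len(group) < 3:
            raise SizeError(
                f"class {label.value} has {len(group)} images, "
                "fewer than the 3 partitions")
        rng.shuffle(group)
        n = len(group)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        parts["train"] += group[:n_train]
        parts["validation"] += group[n_train:n_train + n_val]
        parts["test"] += group[n_train + n_val:]
    return CorpusPartitions(train=parts["train"], validation=parts["validation"],
                            test=parts["test"],
                            split_fractions=tuple(fractions), seed=seed)


def write_manifest(partitions: CorpusPartitions, path: str | Path) -> Path:
    """Emit an audit CSV ``id,label,partition``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label", "partition"])
        for part in ("train", "validation", "test"):
            for im in getattr(partitions, part):
                w.writerow([im.id, im.label.value, part])
    return path
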
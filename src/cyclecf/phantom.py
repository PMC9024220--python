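"""Procedural two-class lung-phantom generator.

Emulates the statistical structure of a frontal chest radiograph at toy
scale: a bright soft-tissue background, two darker elliptical lung fields,
faint periodic rib banding, and — for the diseased class only — smooth
Gaussian opacity blobs confined to the lung fields.  The two classes of a
given seed share identical geometry, banding and pixel noise, so the class
signal is purely textural (added opacity), mirroring a pneumonia/opacity
classification task where lung opacification is the discriminative feature.

Every image is generated from its own RNG stream derived from
``(params.seed, index)``, so corpora are order-independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ParameterError
from .images import Label, LabeledImage

__all__ = ["PhantomParams", "generate_phantom", "make_corpus", "write_corpus"]

_BACKGROUND = 0.85      # soft-tissue intensity
_LUNG_DEPTH = 0.40      # how much darker the lung fields are
_RIB_AMPLITUDE = 0.05   # fixed: saliency non-trivial, class signal dominates


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for the lung phantom.

    ``blob_sigma`` defaults to ``image_size / 8`` when left ``None``.
    """

    image_size: int = 64
    opacity_amplitude: float = 0.35
    n_blobs: int = 3
    blob_sigma: float | None = None
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ParameterError("image_size must be >= 16")
        if not (0.0 <= self.opacity_amplitude <= 1.0):
            raise ParameterError("opacity_amplitude must be in [0, 1]")
        if self.n_blobs < 1:
            raise ParameterError("n_blobs must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.blob_sigma is not None and self.blob_sigma <= 0:
            raise ParameterError("blob_sigma must be positive")

    @property
    def sigma(self) -> float:
        return self.blob_sigma if self.blob_sigma is not None else self.image_size / 8


def _lung_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """Two darker elliptical lung fields with mildly jittered geometry."""
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    mask = np.zeros((size, size), dtype=bool)
    for cx in (0.32, 0.68):
        cx_j = cx + rng.uniform(-0.02, 0.02)
        cy_j = 0.52 + rng.uniform(-0.03, 0.03)
        ax = 0.15 + rng.uniform(-0.015, 0.015)   # semi-axis, x
        ay = 0.30 + rng.uniform(-0.03, 0.03)     # semi-axis, y
        mask |= ((xx - cx_j) / ax) ** 2 + ((yy - cy_j) / ay) ** 2 <= 1.0
    return mask


def _opacity_field(size: int, mask: np.ndarray, params: PhantomParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian blobs centred uniformly inside the lung mask,
    confined to the mask."""
    ys, xs = np.nonzero(mask)
    yy, xx = np.mgrid[0:size, 0:size]
    field = np.zeros((size, size))
    sigma = params.sigma
    for _ in range(params.n_blobs):
        k = rng.integers(len(ys))
        cy, cx = ys[k], xs[k]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        field += params.opacity_amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    return field * mask


def generate_phantom(params: PhantomParams, label: Label,
                     seed: int, image_id: str | None = None) -> LabeledImage:
    """Generate one phantom image.

    The same ``seed`` with different labels yields the *same* geometry,
    rib banding and noise; only the opacity texture differs.
    """
    if not isinstance(label, Label):
        raise ParameterError(f"label must be a Label, got {label!r}")
    geo_ss, blob_ss, noise_ss = np.random.SeedSequence(seed).spawn(3)
    size = params.image_size

    geo = np.random.default_rng(geo_ss)
    mask = _lung_mask(size, geo)
    img = np.full((size, size), _BACKGROUND)
    img -= _LUNG_DEPTH * mask

    yy = np.arange(size)[:, None] / size
    phase = geo.uniform(0, 2 * np.pi)
    img += _RIB_AMPLITUDE * np.sin(2 * np.pi * 6.0 * yy + phase) * np.ones((1, size))

    if label is Label.CLASS_Y:
        img += _opacity_field(size, mask, params, np.random.default_rng(blob_ss))

    if params.noise_sd > 0:
        img += np.random.default_rng(noise_ss).normal(0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    if image_id is None:
        image_id = f"{label.value}-{seed}"
    return LabeledImage(pixels=img.astype(np.float32), label=label, id=image_id)


def lung_mask_for_seed(params: PhantomParams, seed: int) -> np.ndarray:
    """The lung-field mask an image generated from ``seed`` contains
    (identical across labels); exposed for analyses and tests."""
    geo_ss = np.random.SeedSequence(seed).spawn(3)[0]
    return _lung_mask(params.image_size, np.random.default_rng(geo_ss))


def _image_seed(corpus_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([corpus_seed, index]).generate_state(1)[0])


def make_corpus(params: PhantomParams, n_per_class: int) -> list[LabeledImage]:
    """Generate a balanced corpus of ``2 * n_per_class`` phantoms.

    Image ``i`` of the two classes shares geometry and noise (paired seeds),
    so class membership is carried by texture alone.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    corpus: list[LabeledImage] = []
    for label in (Label.CLASS_X, Label.CLASS_Y):
        for i in range(n_per_class):
            corpus.append(generate_phantom(
                params, label, _image_seed(params.seed, i),
                image_id=f"{label.value}-{i:04d}"))
    return corpus


def write_corpus(corpus: list[LabeledImage], root: str | Path) -> Path:
    """Write the corpus as 8-bit grayscale PNGs in ``root/<LABEL>/<id>.png``,
    the directory dialect the loader reads."""
    root = Path(root)
    for label in Label:
        (root / label.value).mkdir(parents=True, exist_ok=True)
    for img in corpus:
        arr = np.round(img.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(root / img.label.value / f"{img.id}.png")
    return root
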
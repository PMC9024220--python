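"""Core domain types: class labels and labeled grayscale images.

Class ``X`` is the "normal" class, class ``Y`` the "opacity"/diseased class,
the convention used consistently by the classifier's one-hot targets and the
counterfactual target vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ParameterError

__all__ = ["Label", "LabeledImage"]


class Label(str, Enum):
    CLASS_X = "CLASS_X"   # normal
    CLASS_Y = "CLASS_Y"   # opacity / diseased

    @property
    def index(self) -> int:
        return 0 if self is Label.CLASS_X else 1

    @property
    def opposite(self) -> "Label":
        return Label.CLASS_Y if self is Label.CLASS_X else Label.CLASS_X


@dataclass(frozen=True)
class LabeledImage:
    """A square grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray
    label: Label
    id: str

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ParameterError(
                f"image {self.id!r} must be square 2-D, got shape {px.shape}")
        if px.size and not (np.isfinite(px).all()
                            and px.min() >= 0.0 and px.max() <= 1.0):
            raise ParameterError(
                f"image {self.id!r} has intensities outside [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]
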
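"""Counterfactual inference and flip-rate evaluation.

An input image is first classified; the generator belonging to the
*predicted* class (G for X, F for Y) then translates it, and the translated
image is classified again.  A counterfactual is *valid* when the predicted
class flips.  The flip-rate report aggregates this over a test set into 2x2
before/after confusion matrices, binned by ground-truth label (the
"Normal" / "Pneumonia" / "Total" presentation), with the flip accuracy of
each subset — the percentage of counterfactuals that actually changed the
classifier's prediction.  Routing uses the predicted class, binning the
true label; the two differ exactly on misclassified inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .classifier import AlexNetSmall, ClassProbability, predict_probabilities
from .exceptions import EvaluationError, ParameterError, ShapeError
from .gan import ResnetGenerator
from .images import Label, LabeledImage
from .nn import Tensor

__all__ = ["CounterfactualResult", "FlipRateReport", "generate_counterfactual",
           "interpolate", "flip_rate_report", "export_explanation"]


@dataclass(frozen=True)
class CounterfactualResult:
    original: np.ndarray
    original_prediction: ClassProbability
    routed_generator: str                 # "G" or "F"
    counterfactual: np.ndarray
    counterfactual_prediction: ClassProbability
    flipped: bool


@dataclass(frozen=True)
class FlipRateReport:
    """Per-class and total before/after confusion counts and flip accuracies.

    Matrix rows are the pre-translation predicted class (X, Y), columns the
    post-translation predicted class; off-diagonal mass is flipped."""

    matrix_normal: np.ndarray
    matrix_pneumonia: np.ndarray
    accuracy_normal: float
    accuracy_pneumonia: float

    @property
    def matrix_total(self) -> np.ndarray:
        return self.matrix_normal + self.matrix_pneumonia

    @property
    def accuracy_total(self) -> float:
        n = self.matrix_normal.sum() + self.matrix_pneumonia.sum()
        flips = (self.matrix_normal.sum() - np.trace(self.matrix_normal)
                 + self.matrix_pneumonia.sum() - np.trace(self.matrix_pneumonia))
        return float(flips / n)

    def to_json(self) -> str:
        return json.dumps({
            "matrix_normal": self.matrix_normal.tolist(),
            "matrix_pneumonia": self.matrix_pneumonia.tolist(),
            "matrix_total": self.matrix_total.tolist(),
            "accuracy_normal": self.accuracy_normal,
            "accuracy_pneumonia": self.accuracy_pneumonia,
            "accuracy_total": self.accuracy_total,
        })


def _pixels(image) -> np.ndarray:
    px = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if px.ndim != 2 or px.shape[0] != px.shape[1]:
        raise ShapeError(f"expected a square 2-D image, got shape {px.shape}")
    return px.astype(np.float32)


def _translate(gen: ResnetGenerator, px: np.ndarray) -> np.ndarray:
    """[0,1] image -> generator ([-1,1] domain) -> [0,1] image."""
    g_in = Tensor((px * 2.0 - 1.0)[None, None, :, :])
    out = gen(g_in).data[0, 0]
    return np.clip((out + 1.0) * 0.5, 0.0, 1.0).astype(np.float32)


def generate_counterfactual(image, classifier: AlexNetSmall,
                            G: ResnetGenerator, F: ResnetGenerator
                            ) -> CounterfactualResult:
    """Route ``image`` through the generator of its *predicted* class and
    re-classify the translation.  Ground-truth labels are never consulted;
    a bare 2-D array works identically to a LabeledImage."""
    px = _pixels(image)
    before = predict_probabilities(classifier, px)
    if before.predicted_label is Label.CLASS_X:
        routed, gen = "G", G
    else:
        routed, gen = "F", F
    cf = _translate(gen, px)
    after = predict_probabilities(classifier, cf)
    return CounterfactualResult(
        original=px, original_prediction=before, routed_generator=routed,
        counterfactual=cf, counterfactual_prediction=after,
        flipped=before.predicted_label is not after.predicted_label)


def interpolate(original, counterfactual, alpha: float) -> np.ndarray:
    """Linear blend ``(1 - alpha) * original + alpha * counterfactual``."""
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    a = np.asarray(original, dtype=np.float32)
    b = np.asarray(counterfactual, dtype=np.float32)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    if alpha == 0.0:
        return a.copy()
    if alpha == 1.0:
        return b.copy()
    return (1.0 - alpha) * a + alpha * b


def flip_rate_report(test: list[LabeledImage], classifier: AlexNetSmall,
                     G: ResnetGenerator, F: ResnetGenerator) -> FlipRateReport:
    """Run counterfactual generation over a labeled test set and tabulate
    before/after predictions per ground-truth subset."""
    if not test:
        raise EvaluationError("test set is empty")
    matrices = {Label.CLASS_X: np.zeros((2, 2), dtype=int),
                Label.CLASS_Y: np.zeros((2, 2), dtype=int)}
    flips = {Label.CLASS_X: 0, Label.CLASS_Y: 0}
    for im in test:
        res = generate_counterfactual(im, classifier, G, F)
        i = res.original_prediction.predicted_label.index
        j = res.counterfactual_prediction.predicted_label.index
        matrices[im.label][i, j] += 1
        flips[im.label] += int(res.flipped)
    for label, name in ((Label.CLASS_X, "normal"), (Label.CLASS_Y, "pneumonia")):
        if matrices[label].sum() == 0:
            raise EvaluationError(f"test set has no images of the "
                                  f"{name} ({label.value}) subset")
    return FlipRateReport(
        matrix_normal=matrices[Label.CLASS_X],
        matrix_pneumonia=matrices[Label.CLASS_Y],
        accuracy_normal=flips[Label.CLASS_X] / matrices[Label.CLASS_X].sum(),
        accuracy_pneumonia=flips[Label.CLASS_Y] / matrices[Label.CLASS_Y].sum(),
    )


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8),
                    mode="L").save(path)


def export_explanation(result: CounterfactualResult, n_frames: int,
                       out: str | Path) -> list[Path]:
    """Write the original, the counterfactual, ``n_frames`` interpolation
    frames, a signed difference map (mid-gray = no change, scaled to the
    full display range) and a JSON sidecar with both predictions."""
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    out = Path(out)
    try:
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, arr in (("original", result.original),
                          ("counterfactual", result.counterfactual)):
            p = out / f"{name}.png"
            _save_png(arr, p)
            written.append(p)
        for k in range(n_frames):
            alpha = k / (n_frames - 1)
            p = out / f"frame_{k:03d}.png"
            _save_png(interpolate(result.original, result.counterfactual, alpha), p)
            written.append(p)
        diff = result.counterfactual.astype(np.float64) - result.original
        peak = np.abs(diff).max()
        disp = np.full_like(diff, 0.5) if peak == 0 else 0.5 + diff / (2 * peak)
        p = out / "difference.png"
        _save_png(disp, p)
        written.append(p)
        sidecar = out / "explanation.json"
        sidecar.write_text(json.dumps({
            "original_prediction": {"p_x": result.original_prediction.p_x,
                                    "p_y": result.original_prediction.p_y},
            "counterfactual_prediction": {
                "p_x": result.counterfactual_prediction.p_x,
                "p_y": result.counterfactual_prediction.p_y},
            "routed_generator": result.routed_generator,
            "flipped": result.flipped,
        }, indent=2))
        written.append(sidecar)
    except OSError as exc:
        raise IOError(f"cannot write explanation to {out}") from exc
    return written
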
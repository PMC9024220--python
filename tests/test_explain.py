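"""Counterfactual routing, interpolation, flip-rate reports, export."""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyclecf import (Label, LabeledImage, flip_rate_report,
                     generate_counterfactual, export_explanation, interpolate,
                     predict_probabilities)
from cyclecf.exceptions import EvaluationError, ParameterError, ShapeError
from cyclecf import nn


class _IdentityGen:
    def __call__(self, x):
        return x


class _OffsetGen:
    """Adds a constant in the [-1, 1] generator domain (then tanh-free)."""

    def __init__(self, delta):
        self.delta = delta

    def __call__(self, x):
        return nn.Tensor(np.clip(x.data + self.delta, -1.0, 1.0))


def _phantom_test_set(classifier32_size=32, n=5):
    from cyclecf.phantom import PhantomParams, make_corpus
    return make_corpus(PhantomParams(image_size=classifier32_size, seed=21), n)


# ------------------------------------------------------------------- routing

def test_identity_generators_do_not_flip(classifier32):
    img = _phantom_test_set()[0]
    res = generate_counterfactual(img, classifier32, _IdentityGen(), _IdentityGen())
    assert res.flipped is False
    assert res.counterfactual_prediction.p_y == pytest.approx(
        res.original_prediction.p_y, abs=1e-6)


def test_routing_follows_prediction_not_label(classifier32):
    """The generator choice depends only on the classifier's prediction;
    a bare unlabeled array routes identically to the labeled image."""
    imgs = _phantom_test_set(n=4)
    for im in imgs:
        pred = predict_probabilities(classifier32, im).predicted_label
        res_labeled = generate_counterfactual(im, classifier32,
                                              _IdentityGen(), _IdentityGen())
        res_raw = generate_counterfactual(im.pixels, classifier32,
                                          _IdentityGen(), _IdentityGen())
        expect = "G" if pred is Label.CLASS_X else "F"
        assert res_labeled.routed_generator == expect
        assert res_raw.routed_generator == expect


def test_counterfactual_output_in_unit_range(classifier32):
    img = _phantom_test_set()[0]
    res = generate_counterfactual(img, classifier32,
                                  _OffsetGen(+5.0), _OffsetGen(-5.0))
    assert res.counterfactual.min() >= 0.0 and res.counterfactual.max() <= 1.0


# -------------------------------------------------------------- interpolation

def test_interpolation_endpoints_bitmatch():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 1, (8, 8)).astype(np.float32)
    b = rng.uniform(0, 1, (8, 8)).astype(np.float32)
    np.testing.assert_array_equal(interpolate(a, b, 0.0), a)
    np.testing.assert_array_equal(interpolate(a, b, 1.0), b)


def test_interpolation_midpoint_arithmetic():
    a = np.full((2, 2), 0.2, dtype=np.float32)
    b = np.full((2, 2), 0.6, dtype=np.float32)
    np.testing.assert_allclose(interpolate(a, b, 0.5), 0.4, atol=1e-7)


@given(alpha=st.floats(0.0, 1.0))
def test_interpolation_stays_between_endpoints(alpha):
    a = np.array([[0.1, 0.9]], dtype=np.float32)
    b = np.array([[0.7, 0.2]], dtype=np.float32)
    out = interpolate(a, b, alpha)
    assert (out >= np.minimum(a, b) - 1e-6).all()
    assert (out <= np.maximum(a, b) + 1e-6).all()


def test_interpolation_validates_inputs():
    a = np.zeros((4, 4))
    with pytest.raises(ParameterError):
        interpolate(a, a, 1.5)
    with pytest.raises(ShapeError):
        interpolate(a, np.zeros((5, 5)), 0.5)


# ------------------------------------------------------------------- reports

def test_identity_generators_give_diagonal_report(classifier32):
    test = _phantom_test_set(n=5)
    report = flip_rate_report(test, classifier32, _IdentityGen(), _IdentityGen())
    assert report.accuracy_total == 0.0
    assert np.trace(report.matrix_normal) == report.matrix_normal.sum()
    assert np.trace(report.matrix_pneumonia) == report.matrix_pneumonia.sum()


def test_report_conservation_and_bruteforce_recount(classifier32):
    """Matrix sums equal subset sizes; the accuracies match an independent
    per-image recount that re-invokes the classifier directly."""
    test = _phantom_test_set(n=5)       # 10 images
    G, F = _OffsetGen(+0.8), _OffsetGen(-0.8)
    report = flip_rate_report(test, classifier32, G, F)
    n_x = sum(im.label is Label.CLASS_X for im in test)
    assert report.matrix_normal.sum() == n_x
    assert report.matrix_pneumonia.sum() == len(test) - n_x
    np.testing.assert_array_equal(report.matrix_total,
                                  report.matrix_normal + report.matrix_pneumonia)
    # brute-force recount, bypassing flip_rate_report
    flips = {Label.CLASS_X: 0, Label.CLASS_Y: 0}
    for im in test:
        before = predict_probabilities(classifier32, im).predicted_label
        gen = G if before is Label.CLASS_X else F
        out = gen(nn.Tensor((im.pixels * 2 - 1)[None, None])).data[0, 0]
        after_img = np.clip((out + 1) / 2, 0, 1)
        after = predict_probabilities(classifier32, after_img).predicted_label
        flips[im.label] += int(before is not after)
    assert report.accuracy_normal == pytest.approx(flips[Label.CLASS_X] / n_x)
    assert report.accuracy_pneumonia == pytest.approx(
        flips[Label.CLASS_Y] / (len(test) - n_x))
    # total accuracy is the count-weighted mean of the per-class accuracies
    weighted = (report.accuracy_normal * n_x
                + report.accuracy_pneumonia * (len(test) - n_x)) / len(test)
    assert report.accuracy_total == pytest.approx(weighted)


def test_report_invariant_to_test_ordering(classifier32):
    test = _phantom_test_set(n=4)
    a = flip_rate_report(test, classifier32, _OffsetGen(0.5), _OffsetGen(-0.5))
    b = flip_rate_report(test[::-1], classifier32,
                         _OffsetGen(0.5), _OffsetGen(-0.5))
    assert a.to_json() == b.to_json()


def test_report_requires_both_label_subsets(classifier32):
    only_x = [im for im in _phantom_test_set(n=3)
              if im.label is Label.CLASS_X]
    with pytest.raises(EvaluationError):
        flip_rate_report(only_x, classifier32, _IdentityGen(), _IdentityGen())
    with pytest.raises(EvaluationError):
        flip_rate_report([], classifier32, _IdentityGen(), _IdentityGen())


# -------------------------------------------------------------------- export

def test_export_two_frames_are_the_endpoints(classifier32, tmp_path):
    img = _phantom_test_set()[0]
    res = generate_counterfactual(img, classifier32,
                                  _OffsetGen(0.6), _OffsetGen(-0.6))
    export_explanation(res, 2, tmp_path)
    from PIL import Image
    f0 = np.asarray(Image.open(tmp_path / "frame_000.png"))
    f1 = np.asarray(Image.open(tmp_path / "frame_001.png"))
    orig = np.asarray(Image.open(tmp_path / "original.png"))
    cf = np.asarray(Image.open(tmp_path / "counterfactual.png"))
    np.testing.assert_array_equal(f0, orig)
    np.testing.assert_array_equal(f1, cf)


def test_export_difference_of_identical_images_is_midgray(classifier32, tmp_path):
    img = _phantom_test_set()[0]
    res = generate_counterfactual(img, classifier32,
                                  _IdentityGen(), _IdentityGen())
    export_explanation(res, 3, tmp_path)
    from PIL import Image
    diff = np.asarray(Image.open(tmp_path / "difference.png"))
    assert np.unique(diff).tolist() == [128]


def test_export_sidecar_roundtrips(classifier32, tmp_path):
    img = _phantom_test_set()[0]
    res = generate_counterfactual(img, classifier32,
                                  _OffsetGen(0.3), _OffsetGen(-0.3))
    export_explanation(res, 4, tmp_path)
    side = json.loads((tmp_path / "explanation.json").read_text())
    assert side["flipped"] == res.flipped
    assert side["original_prediction"]["p_y"] == pytest.approx(
        res.original_prediction.p_y, abs=1e-9)
    assert side["counterfactual_prediction"]["p_x"] == pytest.approx(
        res.counterfactual_prediction.p_x, abs=1e-9)
    with pytest.raises(ParameterError):
        export_explanation(res, 1, tmp_path)
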
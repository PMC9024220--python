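"""Generators, discriminators and the counterfactual training loop:
architecture contracts, gradient isolation, objective bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from cyclecf import (GanConfig, ImagePool, LossWeights, build_discriminator,
                     build_generator, counterfactual_loss, load_gan, save_gan,
                     train_counterfactual_gan)
from cyclecf import nn
from cyclecf.exceptions import (ConfigurationError, ContractError,
                                ParameterError, ShapeError)
from cyclecf.gan import GanBundle, TrainingLog
from cyclecf.presets import desk_classifier

MICRO = GanConfig(image_size=32, base_filters=8, n_residual_blocks=2,
                  epochs=1, seed=0)


@pytest.fixture(scope="module")
def micro_gan_setup(micro_partitions_module):
    parts = micro_partitions_module
    clf = desk_classifier_micro(parts)
    return parts, clf


# module-scoped copies of the micro fixtures so one 5-iteration training
# run can be shared by several tests
@pytest.fixture(scope="module")
def micro_partitions_module():
    from cyclecf import make_corpus, split_corpus
    from cyclecf.presets import phantom_params
    return split_corpus(make_corpus(phantom_params(32, seed=7), 10), seed=7)


def desk_classifier_micro(parts):
    from cyclecf import ClassifierConfig, build_classifier, train_classifier
    cfg = ClassifierConfig(input_size=32, epochs=3, learning_rate=0.01)
    clf = build_classifier(cfg, seed=0)
    train_classifier(clf, parts, cfg, seed=0)
    clf.freeze()
    return clf


@pytest.fixture(scope="module")
def micro_run(micro_gan_setup):
    parts, clf = micro_gan_setup
    checksum_before = clf.checksum()
    bundle = train_counterfactual_gan(parts, clf, MICRO, LossWeights())
    return parts, clf, checksum_before, bundle


# ------------------------------------------------------------- architectures

def test_generator_preserves_shape_and_range():
    g = build_generator(MICRO)
    for size in (16, 32):
        x = nn.Tensor(np.random.default_rng(0).uniform(-1, 1, (1, 1, size, size)))
        out = g(x).data
        assert out.shape == x.shape
        assert out.min() >= -1.0 and out.max() <= 1.0


def test_generator_build_determinism_and_size_validation():
    a = build_generator(MICRO, seed=3)
    b = build_generator(MICRO, seed=3)
    assert a.checksum() == b.checksum()
    with pytest.raises(ConfigurationError):
        build_generator(GanConfig(image_size=30))
    with pytest.raises(ShapeError):
        a(nn.Tensor(np.zeros((1, 1, 30, 30))))


def test_discriminator_outputs_patch_grid():
    d = build_discriminator(MICRO)
    out64 = d(nn.Tensor(np.zeros((1, 1, 64, 64)))).data
    assert out64.shape[2] > 1 and out64.shape[3] > 1
    out128 = d(nn.Tensor(np.zeros((1, 1, 128, 128)))).data
    # fully convolutional: doubling the input doubles each grid dimension
    assert out128.shape[2] == 2 * out64.shape[2]
    assert out128.shape[3] == 2 * out64.shape[3]
    with pytest.raises(ShapeError):
        d(nn.Tensor(np.zeros((1, 1, 12, 12))))


def test_discriminator_translation_equivariance():
    """Shifting a delta impulse by one patch stride (8 px) shifts the score
    grid by one cell, away from the borders."""
    d = build_discriminator(MICRO, seed=1)
    base = np.zeros((1, 1, 64, 64), dtype=np.float32)
    a = base.copy()
    a[0, 0, 24, 24] = 1.0
    b = base.copy()
    b[0, 0, 32, 32] = 1.0
    ga = d(nn.Tensor(a)).data[0, 0]
    gb = d(nn.Tensor(b)).data[0, 0]
    raw = np.abs(ga - gb).max()
    shifted = np.abs(ga[2:-3, 2:-3] - gb[3:-2, 3:-2]).max()
    # instance-norm statistics couple cells mildly: approximate equivariance
    assert shifted < 0.1 * raw


# ------------------------------------------------------------------ training

def test_frozen_classifier_contract(micro_gan_setup):
    parts, _ = micro_gan_setup
    unfrozen = desk_classifier_micro(parts)
    for p in unfrozen.parameters():
        p.requires_grad = True
    with pytest.raises(ContractError):
        train_counterfactual_gan(parts, unfrozen, MICRO)


def test_counterfactual_gradient_isolation(micro_gan_setup):
    """The counterfactual term moves generator parameters but never the
    frozen classifier's."""
    parts, clf = micro_gan_setup
    g = build_generator(MICRO, seed=0)
    x = nn.Tensor((parts.train[0].pixels * 2 - 1)[None, None, :, :])
    fake = g(x)
    probs = clf((fake + 1.0) * 0.5)
    loss = counterfactual_loss(probs, np.array([[1.0, 0.0]]))
    loss.backward()
    assert all(p.grad is None for p in clf.parameters())
    gen_grads = [p.grad for p in g.parameters() if p.grad is not None]
    assert gen_grads and any(np.abs(gr).max() > 0 for gr in gen_grads)


def test_classifier_untouched_and_log_bookkeeping(micro_run):
    parts, clf, checksum_before, bundle = micro_run
    assert clf.checksum() == checksum_before
    xs = len(parts.by_label("train", __import__("cyclecf").Label.CLASS_X))
    ys = len(parts.by_label("train", __import__("cyclecf").Label.CLASS_Y))
    assert len(bundle.log) == min(xs, ys) * MICRO.epochs
    for rec in bundle.log.records:
        expected = (rec["adv_g"] + rec["adv_f"] + 10.0 * rec["cycle"]
                    + 1.0 * rec["identity"] + 1.0 * rec["counter"])
        assert rec["total"] == pytest.approx(expected, abs=1e-5)
        assert all(np.isfinite(v) for v in rec.values())


def test_seeded_runs_reproduce_training_log(micro_gan_setup):
    parts, clf = micro_gan_setup
    log1 = train_counterfactual_gan(parts, clf, MICRO).log
    log2 = train_counterfactual_gan(parts, clf, MICRO).log
    assert log1.records == log2.records


def test_gamma_zero_still_logs_counterfactual_term(micro_gan_setup):
    parts, clf = micro_gan_setup
    bundle = train_counterfactual_gan(parts, clf, MICRO,
                                      LossWeights(gamma_counter=0.0))
    for rec in bundle.log.records:
        assert "counter" in rec
        expected = (rec["adv_g"] + rec["adv_f"] + 10.0 * rec["cycle"]
                    + rec["identity"])          # counter carries zero weight
        assert rec["total"] == pytest.approx(expected, abs=1e-5)


def test_log_adversarial_form_trains(micro_gan_setup):
    parts, clf = micro_gan_setup
    cfg = GanConfig(image_size=32, base_filters=8, n_residual_blocks=1,
                    epochs=1, adversarial_form="log", seed=0)
    bundle = train_counterfactual_gan(parts, clf, cfg)
    assert all(np.isfinite(r["total"]) for r in bundle.log.records)


def test_training_log_csv_roundtrip(micro_run, tmp_path):
    *_, bundle = micro_run
    path = bundle.log.to_csv(tmp_path / "log.csv")
    rows = path.read_text().strip().splitlines()
    assert len(rows) == len(bundle.log) + 1
    assert rows[0].split(",")[0] == "iteration"


def test_gan_checkpoint_roundtrip(micro_run, tmp_path):
    *_, bundle = micro_run
    path = save_gan(bundle, tmp_path / "gan.npz")
    loaded = load_gan(path)
    probe = nn.Tensor(np.random.default_rng(5).uniform(-1, 1, (1, 1, 32, 32)))
    np.testing.assert_array_equal(bundle.G(probe).data, loaded.G(probe).data)
    np.testing.assert_array_equal(bundle.F(probe).data, loaded.F(probe).data)


def test_image_pool_behaviour():
    rng = np.random.default_rng(0)
    pool = ImagePool(2, rng)
    a, b, c = (np.full((1, 1, 2, 2), v, dtype=np.float32) for v in (1.0, 2.0, 3.0))
    assert pool.query(a) is a            # filling phase returns the input
    assert pool.query(b) is b
    seen = {float(pool.query(c).ravel()[0]) for _ in range(20)}
    assert seen <= {1.0, 2.0, 3.0}       # either the input or a stored image
    none_pool = ImagePool(0, rng)
    assert none_pool.query(a) is a


def test_config_validation():
    with pytest.raises(ParameterError):
        GanConfig(learning_rate=0.0)
    with pytest.raises(ParameterError):
        GanConfig(adversarial_form="wasserstein")
    with pytest.raises(ParameterError):
        GanConfig(target_g=(0.5, 0.6))
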
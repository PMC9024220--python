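"""Shared fixtures: desk-scale corpora, trained classifiers, GAN runs.

The expensive artifacts (trained networks) are session-scoped so the whole
suite trains each of them exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cyclecf import (GanConfig, Label, LabeledImage, LossWeights,
                     flip_rate_report, make_corpus, split_corpus,
                     train_counterfactual_gan)
from cyclecf.presets import (N_PER_CLASS_32, N_PER_CLASS_64, desk_classifier,
                             gan_config, phantom_params)

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

GAN_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def corpus32():
    return make_corpus(phantom_params(32, seed=0), N_PER_CLASS_32)


@pytest.fixture(scope="session")
def partitions32(corpus32):
    return split_corpus(corpus32, seed=0)


@pytest.fixture(scope="session")
def classifier32(partitions32):
    """Trained, frozen 32 px companion classifier for the GAN experiments."""
    clf = desk_classifier(partitions32, 32, seed=0)
    clf.freeze()
    return clf


@pytest.fixture(scope="session")
def corpus64():
    return make_corpus(phantom_params(64, seed=0), N_PER_CLASS_64)


@pytest.fixture(scope="session")
def partitions64(corpus64):
    return split_corpus(corpus64, seed=0)


@pytest.fixture(scope="session")
def classifier64(partitions64):
    return desk_classifier(partitions64, 64, seed=0)


@pytest.fixture(scope="session")
def gan_runs(partitions32, classifier32):
    """Counterfactual (gamma=1) and vanilla (gamma=0) runs at three seeds.

    Returns ``{(seed, gamma): (bundle, flip_rate_report)}`` on the held-out
    test partition.
    """
    runs = {}
    for seed in GAN_SEEDS:
        for gamma in (1.0, 0.0):
            weights = LossWeights(gamma_counter=gamma)
            bundle = train_counterfactual_gan(
                partitions32, classifier32, gan_config(seed=seed), weights)
            report = flip_rate_report(partitions32.test, classifier32,
                                      bundle.G, bundle.F)
            runs[(seed, gamma)] = (bundle, report)
    return runs


@pytest.fixture()
def micro_partitions():
    """A very small 32 px split for fast contract tests."""
    corpus = make_corpus(phantom_params(32, seed=7), 10)
    return split_corpus(corpus, seed=7)


def shuffle_labels(corpus: list[LabeledImage], seed: int) -> list[LabeledImage]:
    """Permute labels across the corpus (null-signal control)."""
    rng = np.random.default_rng(seed)
    labels = [im.label for im in corpus]
    perm = rng.permutation(len(labels))
    return [LabeledImage(pixels=im.pixels, label=labels[perm[i]], id=im.id)
            for i, im in enumerate(corpus)]
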
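"""Desk-scale study conditions shared by the test-suite, the acceptance
script and the examples.

Two tiers, both small enough for a single CPU:

* classifier tier — 64 px phantoms, 200 images per class, 30 training
  epochs: the corpus a compact CNN should separate almost perfectly.
* translation tier — 32 px phantoms, 100 images per class; the
  counterfactual CycleGAN trains for 5 epochs with base width 16 and
  6 residual blocks, against a frozen companion classifier trained on the
  same corpus.

The SGD learning rate for these short runs is 0.01 (the full-scale recipe's
1e-4 belongs to a 1000-epoch schedule).  All randomness derives from the
single ``seed`` argument.
"""

from __future__ import annotations

from .classifier import (AlexNetSmall, ClassifierConfig, build_classifier,
                         train_classifier)
from .data import CorpusPartitions, split_corpus
from .gan import GanConfig
from .phantom import PhantomParams, make_corpus

__all__ = [
    "phantom_params", "classifier_config", "gan_config",
    "desk_corpus", "desk_classifier",
    "N_PER_CLASS_64", "N_PER_CLASS_32",
]

N_PER_CLASS_64 = 200
N_PER_CLASS_32 = 100


def phantom_params(image_size: int, seed: int = 0) -> PhantomParams:
    return PhantomParams(image_size=image_size, seed=seed)


def classifier_config(image_size: int) -> ClassifierConfig:
    epochs = 30 if image_size >= 64 else 20
    return ClassifierConfig(input_size=image_size, epochs=epochs,
                            learning_rate=0.01)


def gan_config(seed: int = 0, epochs: int = 5) -> GanConfig:
    """Translation-tier configuration (32 px)."""
    return GanConfig(image_size=32, base_filters=16, n_residual_blocks=6,
                     epochs=epochs, seed=seed)


def desk_corpus(image_size: int, seed: int = 0) -> CorpusPartitions:
    n = N_PER_CLASS_64 if image_size >= 64 else N_PER_CLASS_32
    corpus = make_corpus(phantom_params(image_size, seed), n)
    return split_corpus(corpus, seed=seed)


def desk_classifier(partitions: CorpusPartitions, image_size: int,
                    seed: int = 0) -> AlexNetSmall:
    """Build and train the tier's classifier (not frozen)."""
    config = classifier_config(image_size)
    clf = build_classifier(config, seed=seed)
    train_classifier(clf, partitions, config, seed=seed)
    return clf
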
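"""Shared fixtures: a synthetic corpus and models trained on it once per session."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from rfcottnet.data import (CCDPHD11_CLASSES, ClassSpec,
                            default_class_signatures,
                            generate_synthetic_dataset, stratified_split)
from rfcottnet.models import attach_exit_heads, build_backbone, tiny_config
from rfcottnet.quant import QuantSpec, insert_fake_quant, qat_finetune
from rfcottnet.training import load_arrays, train_model

# desk-scale study conditions: 30 images per class at 64 x 64, width/8 model,
# 30 epochs of batch-32 AdamW at 5e-3 with cosine decay
N_PER_CLASS = 30
IMAGE_SIZE = 64
TRAIN_EPOCHS = 30


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Synthetic 11-class corpus with a stratified 8:2 split."""
    root = tmp_path_factory.mktemp("corpus")
    sigs = default_class_signatures()
    specs = [ClassSpec(name, N_PER_CLASS, sigs[name]) for name in CCDPHD11_CLASSES]
    manifest = generate_synthetic_dataset(specs, root, IMAGE_SIZE, seed=7)
    return stratified_split(manifest, 0.8, seed=7)


@pytest.fixture(scope="session")
def corpus_arrays(corpus):
    xtr, ytr = load_arrays(corpus, "train")
    xte, yte = load_arrays(corpus, "test")
    return xtr, ytr, xte, yte


@pytest.fixture(scope="session")
def trained_tiny(corpus_arrays):
    """Tiny multi-exit model trained to convergence on the synthetic corpus."""
    xtr, ytr, _, _ = corpus_arrays
    model = attach_exit_heads(build_backbone(tiny_config(), seed=3),
                              head_width=48, seed=4)
    train_model(model, xtr, ytr, epochs=TRAIN_EPOCHS, batch_size=32,
                lr=5e-3, seed=5)
    return model


@pytest.fixture(scope="session")
def qat_tiny(trained_tiny, corpus_arrays):
    """Fake-quantized copy of the trained model, fine-tuned and frozen."""
    xtr, ytr, _, _ = corpus_arrays
    model = copy.deepcopy(trained_tiny)
    insert_fake_quant(model, QuantSpec())
    qat_finetune(model, xtr, ytr, epochs=2, seed=6, lr=5e-4)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
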
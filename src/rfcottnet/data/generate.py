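"""Synthetic corpus generation (stand-in for the real 11-class leaf corpus)."""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
from PIL import Image

from .renderer import render_leaf
from .types import (CCDPHD11_CLASS_TOTALS, ClassSpec, DatasetManifest,
                    ImageSample, default_class_signatures)


def scaled_ccdphd11_specs(scale: float = 1 / 20) -> list[ClassSpec]:
    """Class specs with the published per-class totals scaled down (rounded)."""
    sigs = default_class_signatures()
    return [ClassSpec(name, int(round(n * scale)), sigs[name])
            for name, n in CCDPHD11_CLASS_TOTALS.items()]


def generate_synthetic_dataset(class_specs: Sequence[ClassSpec],
                               out_dir: str | os.PathLike,
                               image_size: int = 64, seed: int = 0,
                               image_format: str = "png",
                               source: str = "synthetic") -> DatasetManifest:
    """Render ``n_images`` per class into one directory per class.

    Deterministic for a fixed seed: every image gets its own child stream of
    a splittable seed sequence, so per-class counts can change without
    perturbing other classes' imagery.
    """
    names = [cs.name for cs in class_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names in class_specs")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    root = np.random.SeedSequence(seed)
    samples: list[ImageSample] = []
    for ci, cs in enumerate(class_specs):
        cls_dir = os.path.join(out_dir, cs.name)
        os.makedirs(cls_dir, exist_ok=True)
        class_seq = np.random.SeedSequence(entropy=root.entropy, spawn_key=(ci,))
        for k, child in enumerate(class_seq.spawn(cs.n_images)):
            rng = np.random.default_rng(child)
            img = render_leaf(cs.visual_signature, image_size, rng)
            path = os.path.join(cls_dir, f"{cs.name.replace(' ', '_').lower()}_{k:05d}.{image_format}")
            im = Image.fromarray(img)
            if image_format in ("jpg", "jpeg"):
                im.save(path, quality=95)
            else:
                im.save(path)
            samples.append(ImageSample(path, cs.name, source))
    return DatasetManifest(samples, tuple(names), seed)
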
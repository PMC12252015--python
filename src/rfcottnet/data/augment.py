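"""Stochastic image augmentation: brightness, flips, masking, noise, rotation.

Every variant applies an independently sampled non-empty subset of the five
operators; sampled parameters are returned alongside the images so a test (or
a curious user) can re-apply them independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image

from .types import AugmentationPolicy, DatasetManifest, ImageSample


@dataclass
class AugmentationParams:
    """The concrete draw for one variant; ``None`` means operator not applied."""

    brightness: float | None = None        # multiplicative factor
    flip: str | None = None                # "horizontal" | "vertical"
    masks: list[tuple[int, int, int, int]] = field(default_factory=list)  # x, y, w, h
    noise_seed: int | None = None
    noise_sigma: float = 0.0
    rotation: float | None = None          # degrees, counter-clockwise

    @property
    def is_identity(self) -> bool:
        return (self.brightness is None and self.flip is None and not self.masks
                and self.noise_seed is None and self.rotation is None)


def rotate_image(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate by ``angle`` degrees (bilinear, same canvas, black fill)."""
    return np.asarray(Image.fromarray(image).rotate(angle, resample=Image.BILINEAR))


def sample_augmentation(policy: AugmentationPolicy, image_shape: tuple[int, int],
                        rng: np.random.Generator) -> AugmentationParams:
    """Draw one operator subset and its parameters.

    Operators whose policy strength is an identity value (zero delta/sigma,
    empty flip set, zero-size masks) are excluded from the draw; among the
    active ones, at least one is always applied.
    """
    h, w = image_shape
    active = []
    if policy.brightness_delta > 0:
        active.append("brightness")
    if policy.flip_modes:
        active.append("flip")
    if policy.mask_size_range[1] > 0:
        active.append("mask")
    if policy.noise_sigma > 0:
        active.append("noise")
    if policy.rotation_range > 0:
        active.append("rotation")
    if not active:
        return AugmentationParams()
    chosen = [op for op in active if rng.random() < 0.5]
    if not chosen:
        chosen = [active[int(rng.integers(len(active)))]]

    params = AugmentationParams()
    if "brightness" in chosen:
        params.brightness = 1.0 + rng.uniform(-policy.brightness_delta,
                                              policy.brightness_delta)
    if "flip" in chosen:
        params.flip = policy.flip_modes[int(rng.integers(len(policy.flip_modes)))]
    if "mask" in chosen:
        count = int(rng.integers(policy.mask_count_range[0],
                                 policy.mask_count_range[1] + 1))
        side = min(h, w)
        for _ in range(count):
            mw = max(1, int(rng.uniform(*policy.mask_size_range) * side))
            mh = max(1, int(rng.uniform(*policy.mask_size_range) * side))
            x = int(rng.integers(0, max(1, w - mw)))
            y = int(rng.integers(0, max(1, h - mh)))
            params.masks.append((x, y, mw, mh))
    if "noise" in chosen:
        params.noise_seed = int(rng.integers(0, 2**31))
        params.noise_sigma = policy.noise_sigma
    if "rotation" in chosen:
        params.rotation = float(rng.uniform(-policy.rotation_range,
                                            policy.rotation_range))
    return params


def apply_augmentation(image: np.ndarray, params: AugmentationParams) -> np.ndarray:
    """Apply a sampled draw: brightness -> flip -> rotation -> masks -> noise."""
    out = image.astype(np.float64)
    if params.brightness is not None:
        out = out * params.brightness
    out = np.clip(out, 0, 255).astype(np.uint8)
    if params.flip == "horizontal":
        out = out[:, ::-1]
    elif params.flip == "vertical":
        out = out[::-1]
    if params.rotation is not None:
        out = rotate_image(np.ascontiguousarray(out), params.rotation)
    out = out.copy()
    for x, y, mw, mh in params.masks:
        out[y:y + mh, x:x + mw] = 0
    if params.noise_seed is not None:
        noise = np.random.default_rng(params.noise_seed).normal(
            0.0, params.noise_sigma, out.shape)
        out = np.clip(out.astype(np.float64) + noise, 0, 255).astype(np.uint8)
    return out


def augment_image(image: np.ndarray, policy: AugmentationPolicy, seed: int,
                  return_params: bool = False):
    """Produce ``policy.variants_per_original`` images, the original first."""
    if image.size == 0:
        raise ValueError("empty image")
    rng = np.random.default_rng(seed)
    images = [image.copy()]
    all_params = [AugmentationParams()]
    for _ in range(policy.variants_per_original - 1):
        p = sample_augmentation(policy, image.shape[:2], rng)
        images.append(apply_augmentation(image, p))
        all_params.append(p)
    return (images, all_params) if return_params else images


def augment_dataset(manifest: DatasetManifest, policy: AugmentationPolicy,
                    seed: int, out_dir: str | os.PathLike,
                    image_format: str = "png") -> DatasetManifest:
    """Expand every sample into its variants, all tagged ``source=augmented``.

    Output count = variants_per_original x input count; the re-saved original
    is included and re-tagged, matching the corpus accounting where the 4,776
    augmented images include the 796 originals.
    """
    out_dir = os.fspath(out_dir)
    children = np.random.SeedSequence(seed).spawn(max(len(manifest.samples), 1))
    out_samples: list[ImageSample] = []
    for sample, ss in zip(manifest.samples, children):
        image = np.asarray(Image.open(sample.path).convert("RGB"))
        variants = augment_image(image, policy, int(ss.generate_state(1)[0] % 2**31))
        cls_dir = os.path.join(out_dir, sample.label)
        os.makedirs(cls_dir, exist_ok=True)
        stem = os.path.splitext(os.path.basename(sample.path))[0]
        for k, var in enumerate(variants):
            path = os.path.join(cls_dir, f"{stem}_aug{k}.{image_format}")
            im = Image.fromarray(var)
            if image_format in ("jpg", "jpeg"):
                im.save(path, quality=95)
            else:
                im.save(path)
            out_samples.append(ImageSample(path, sample.label, "augmented",
                                           sample.split))
    return DatasetManifest(out_samples, manifest.classes, seed)


def merge_manifests(*manifests: DatasetManifest) -> DatasetManifest:
    """Concatenate manifests sharing one class list."""
    classes = manifests[0].classes
    for m in manifests[1:]:
        if m.classes != classes:
            raise ValueError("cannot merge manifests with different class lists")
    samples = [replace(s) for m in manifests for s in m.samples]
    return DatasetManifest(samples, classes, manifests[0].seed)
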
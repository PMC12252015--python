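"""Synthetic cotton-leaf image renderer.

Draws an elliptical leaf with a midrib on a textured background; class
identity is encoded by the lesion count, lesion hue, leaf/background hues and
texture noise of the class's :class:`VisualSignature`.  Purely synthetic stand
-in imagery: it emulates the class structure of a leaf-disease corpus, not
real disease morphology.
"""

from __future__ import annotations

import colorsys

import numpy as np

from .types import VisualSignature


def _hsv_rgb(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, s, v)) * 255.0


def render_leaf(signature: VisualSignature, image_size: int,
                rng: np.random.Generator) -> np.ndarray:
    """Render one H x W x 3 uint8 leaf image."""
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    n = image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64) / (n - 1) - 0.5

    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = _hsv_rgb(signature.background_hue, 0.45, 0.55)

    # slowly varying background texture
    bg_phase = rng.uniform(0, 2 * np.pi, 2)
    tex = 12.0 * np.sin(6.0 * np.pi * xx + bg_phase[0]) * np.cos(5.0 * np.pi * yy + bg_phase[1])
    img += tex[..., None]

    # elliptical leaf, randomly rotated and slightly scaled
    theta = rng.uniform(-0.5, 0.5)
    a = rng.uniform(0.32, 0.40)
    b = rng.uniform(0.20, 0.27)
    c, s = np.cos(theta), np.sin(theta)
    xr = c * xx + s * yy
    yr = -s * xx + c * yy
    leaf = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    leaf_col = _hsv_rgb(signature.leaf_hue, 0.70, rng.uniform(0.55, 0.70))
    img[leaf] = leaf_col
    # midrib and veins
    rib = leaf & (np.abs(yr) < 0.01)
    img[rib] = leaf_col * 0.6
    for k in (-2, -1, 1, 2):
        vein = leaf & (np.abs(yr - 0.09 * k - 0.35 * xr * np.sign(k)) < 0.006)
        img[vein] = leaf_col * 0.75

    # lesions on the leaf
    lo, hi = signature.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    for _ in range(n_lesions):
        # rejection-sample a center on the leaf
        for _attempt in range(50):
            cx, cy = rng.uniform(-0.4, 0.4, 2)
            if (c * cx + s * cy) ** 2 / a ** 2 + (-s * cx + c * cy) ** 2 / b ** 2 <= 0.8:
                break
        r = rng.uniform(*signature.lesion_size_range)
        spot = ((xx - cx) ** 2 + (yy - cy) ** 2) <= r ** 2
        col = _hsv_rgb(signature.lesion_hue, 0.85, rng.uniform(0.45, 0.75))
        img[spot & leaf] = col
        ring = spot & ~(((xx - cx) ** 2 + (yy - cy) ** 2) <= (0.7 * r) ** 2) & leaf
        img[ring] = col * 0.6

    if signature.texture_noise_sigma > 0:
        img += rng.normal(0.0, signature.texture_noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
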
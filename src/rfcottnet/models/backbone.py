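"""MobileViTv2-style hybrid backbone.

Stem 3x3 convolution, a stack of MobileNetV2 inverted-residual blocks (MV2B)
for local features, and three MobileViT stages whose transformer layers use
separable self-attention for global modeling.  The three MobileViT stages
expose tap points t1, t2, t3 for the auxiliary exit heads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import (BatchNorm2d, Conv2d, GlobalAvgPool, Identity,
                          LayerNorm, Linear, Module, Sequential, SiLU)
from .attention import SeparableSelfAttention


@dataclass
class MobileViTStage:
    out_channels: int
    attn_dim: int
    depth: int


@dataclass
class BackboneConfig:
    """Stage table of the backbone; widths scale with ``width_multiplier``.

    The defaults follow the 1.0-width MobileViTv2 design: stem 32, MV2 64,
    MV2 128 (x2, first downsampling), then three [MV2-down + MobileViT]
    stages at 256/384/512 channels with attention widths 128/192/256 and
    transformer depths 2/4/3.
    """

    width_multiplier: float = 1.0
    num_classes: int = 11
    image_size: int = 256
    patch_size: int = 2
    expansion: int = 2
    stem_channels: int = 32
    mv2_channels: tuple[int, int] = (64, 128)
    mobilevit_stages: tuple[MobileViTStage, ...] = (
        MobileViTStage(256, 128, 2),
        MobileViTStage(384, 192, 4),
        MobileViTStage(512, 256, 3),
    )
    ffn_multiplier: int = 2

    def scaled(self, c: int) -> int:
        return max(4, int(round(c * self.width_multiplier)))


def full_config(num_classes: int = 11) -> BackboneConfig:
    return BackboneConfig(num_classes=num_classes)


def tiny_config(num_classes: int = 11, image_size: int = 64) -> BackboneConfig:
    """Desk-scale preset: widths / 8 at 64 x 64 input."""
    return BackboneConfig(width_multiplier=0.125, num_classes=num_classes,
                          image_size=image_size)


class MV2Block(Module):
    """Inverted residual: pointwise expand -> depthwise 3x3 -> project.

    Residual connection added iff stride is 1 and input width equals output
    width; stride 2 halves the spatial size.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1, expansion: int = 2,
                 *, rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"invalid stride {stride}")
        rng = rng or np.random.default_rng()
        hidden = cin * expansion
        self.use_residual = stride == 1 and cin == cout
        layers: list[Module] = []
        if expansion != 1:
            layers += [Conv2d(cin, hidden, 1, bias=False, rng=rng),
                       BatchNorm2d(hidden), SiLU()]
        layers += [Conv2d(hidden, hidden, 3, stride=stride, padding=1,
                          groups=hidden, bias=False, rng=rng),
                   BatchNorm2d(hidden), SiLU(),
                   Conv2d(hidden, cout, 1, bias=False, rng=rng),
                   BatchNorm2d(cout)]
        self.block = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block(x)
        if self.use_residual:
            out = ag.add(out, x)
        return out


class TransformerLayer(Module):
    """Pre-norm separable attention + pre-norm feed-forward, both residual."""

    def __init__(self, dim: int, ffn_dim: int, *, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = SeparableSelfAttention(dim, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = Sequential(Linear(dim, ffn_dim, rng=rng), SiLU(),
                              Linear(ffn_dim, dim, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        x = ag.add(x, self.attn(self.norm1(x)))
        x = ag.add(x, self.ffn(self.norm2(x)))
        return x


def unfold_tokens(x: Tensor, patch: int) -> Tensor:
    """(N, C, H, W) -> (N, p*p, HW/p^2, C): one token group per intra-patch
    offset, one token per patch position."""
    n, c, h, w = x.shape
    if h % patch or w % patch:
        x = ag.pad2d(x, (0, (-h) % patch, 0, (-w) % patch))
        n, c, h, w = x.shape
    x = ag.reshape(x, (n, c, h // patch, patch, w // patch, patch))
    x = ag.transpose(x, (0, 3, 5, 2, 4, 1))
    return ag.reshape(x, (n, patch * patch, (h // patch) * (w // patch), c))


def fold_tokens(x: Tensor, patch: int, hw: tuple[int, int]) -> Tensor:
    """Inverse of :func:`unfold_tokens` (exact round trip)."""
    n, p2, k, c = x.shape
    h, w = hw
    hp, wp = h // patch, w // patch
    x = ag.reshape(x, (n, patch, patch, hp, wp, c))
    x = ag.transpose(x, (0, 5, 3, 1, 4, 2))
    return ag.reshape(x, (n, c, h, w))


class MobileViTBlock(Module):
    """Local conv -> unfold -> transformer stack -> fold -> project + fuse."""

    def __init__(self, cin: int, attn_dim: int, depth: int, patch: int = 2,
                 ffn_multiplier: int = 2, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.patch = patch
        self.local_dw = Sequential(
            Conv2d(cin, cin, 3, padding=1, groups=cin, bias=False, rng=rng),
            BatchNorm2d(cin), SiLU())
        self.local_pw = Conv2d(cin, attn_dim, 1, bias=False, rng=rng)
        self.transformer = Sequential(*[
            TransformerLayer(attn_dim, ffn_multiplier * attn_dim, rng=rng)
            for _ in range(depth)])
        self.norm = LayerNorm(attn_dim) if depth else Identity()
        self.proj = Sequential(Conv2d(attn_dim, cin, 1, bias=False, rng=rng),
                               BatchNorm2d(cin))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        hp = h + (-h) % self.patch
        wp = w + (-w) % self.patch
        local = self.local_pw(self.local_dw(x))
        tokens = unfold_tokens(local, self.patch)
        tokens = self.norm(self.transformer(tokens))
        feat = fold_tokens(tokens, self.patch, (hp, wp))
        if (hp, wp) != (h, w):
            feat = Tensor(feat.data[:, :, :h, :w]) if not feat.requires_grad \
                else _crop(feat, h, w)
        out = self.proj(feat)
        return ag.add(out, x)


def _crop(t: Tensor, h: int, w: int) -> Tensor:
    """Differentiable top-left spatial crop (adjoint zero-pads)."""
    out = Tensor(t.data[:, :, :h, :w])
    out.requires_grad = True
    out._parents = (t,)

    def bw():
        g = np.zeros_like(t.data)
        g[:, :, :h, :w] = out.grad
        t._accumulate(g)

    out._backward = bw
    return out


class Backbone(Module):
    """Feature extractor with named tap points t1-t3 and a final head."""

    def __init__(self, cfg: BackboneConfig, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        sc = cfg.scaled
        c0 = sc(cfg.stem_channels)
        c1, c2 = (sc(c) for c in cfg.mv2_channels)
        self.stem = Sequential(Conv2d(3, c0, 3, stride=2, padding=1, bias=False,
                                      rng=rng), BatchNorm2d(c0), SiLU())
        self.layer1 = MV2Block(c0, c1, 1, cfg.expansion, rng=rng)
        self.layer2 = Sequential(MV2Block(c1, c2, 2, cfg.expansion, rng=rng),
                                 MV2Block(c2, c2, 1, cfg.expansion, rng=rng))
        stages = []
        prev = c2
        self.tap_channels: list[int] = []
        for st in cfg.mobilevit_stages:
            cout, d = sc(st.out_channels), sc(st.attn_dim)
            stages.append(Sequential(
                MV2Block(prev, cout, 2, cfg.expansion, rng=rng),
                MobileViTBlock(cout, d, st.depth, cfg.patch_size,
                               cfg.ffn_multiplier, rng=rng)))
            prev = cout
            self.tap_channels.append(cout)
        self.vit_stages = stages
        self.pool = GlobalAvgPool()
        self.classifier = Linear(prev, cfg.num_classes, rng=rng)

    def forward_features(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run the trunk; returns ([t1, t2, t3], pooled final features)."""
        x = self.layer2(self.layer1(self.stem(x)))
        taps = []
        for stage in self.vit_stages:
            x = stage(x)
            taps.append(x)
        return taps, self.pool(x)

    def forward(self, x: Tensor) -> Tensor:
        _, feat = self.forward_features(x)
        return self.classifier(feat)


def build_backbone(cfg: BackboneConfig, num_classes: int | None = None,
                   seed: int = 0) -> Backbone:
    """Construct a backbone with deterministic (seeded) initialization."""
    if num_classes is not None and num_classes != cfg.num_classes:
        cfg = replace(cfg, num_classes=num_classes)
    return Backbone(cfg, rng=np.random.default_rng(seed))
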
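"""Multi-exit model: auxiliary heads, joint loss, threshold-gated inference.

Three lightweight classification heads tap the backbone after each MobileViT
stage; a fourth "stage" is the backbone's own classifier.  During training
every stage carries its own cross-entropy loss and the total is a weighted
sum.  During inference a sample leaves at the first stage whose gate passes:
either softmax confidence strictly above a per-stage threshold (defaults
0.6 / 0.7 / 0.8) or prediction entropy strictly below a threshold S; the
final stage always exits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import (Conv2d, GlobalAvgPool, Linear, Module, ReLU,
                          Sequential)
from .backbone import Backbone

#: exit-head width chosen so that the full-width model (backbone + three
#: heads + final classifier) lands on the published 4.9 M parameter budget
#: while its INT8 export stays inside the 4.8 MB storage budget
DEFAULT_HEAD_WIDTH = 400


def entropy(probs: np.ndarray) -> float | np.ndarray:
    """Shannon entropy in nats, -sum p ln p with 0 ln 0 = 0.

    Accepts a single simplex vector or a batch (last axis = classes).
    """
    p = np.asarray(probs, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("negative probability entries")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1)
    return float(h) if h.ndim == 0 else h


@dataclass
class StagePrediction:
    """Prediction emitted by one exit stage for one sample."""

    stage_index: int            # 1-based
    logits: np.ndarray
    probs: np.ndarray
    entropy: float
    confidence: float
    exited: bool = True

    @classmethod
    def from_logits(cls, stage_index: int, logits: np.ndarray,
                    exited: bool = True) -> "StagePrediction":
        z = logits - logits.max()
        p = np.exp(z)
        p /= p.sum()
        return cls(stage_index, logits, p, entropy(p), float(p.max()), exited)

    @property
    def label_index(self) -> int:
        return int(np.argmax(self.probs))


@dataclass
class ExitPolicy:
    """Gate definition for dynamic inference.

    ``confidence`` mode exits at the first stage whose max softmax probability
    strictly exceeds its threshold; ``entropy`` mode exits where prediction
    entropy falls strictly below the threshold.  The final stage always exits.
    """

    mode: str = "confidence"
    thresholds: tuple[float, ...] = (0.6, 0.7, 0.8)
    n_stages: int = 4

    def __post_init__(self):
        if self.mode not in ("confidence", "entropy"):
            raise ValueError(f"unknown exit mode {self.mode!r}")
        th = self.thresholds
        if np.isscalar(th):
            th = (float(th),) * (self.n_stages - 1)
        self.thresholds = tuple(float(t) for t in th)
        if len(self.thresholds) == 1 and self.n_stages > 2:
            self.thresholds = self.thresholds * (self.n_stages - 1)
        if len(self.thresholds) != self.n_stages - 1:
            raise ValueError("need one threshold per non-final stage")
        if self.mode == "entropy" and any(t < 0 for t in self.thresholds):
            raise ValueError("entropy thresholds must be >= 0")

    def passes(self, pred: StagePrediction) -> bool:
        i = pred.stage_index - 1
        if i >= self.n_stages - 1:
            return True
        if self.mode == "confidence":
            return pred.confidence > self.thresholds[i]
        return pred.entropy < self.thresholds[i]


class ExitHead(Module):
    """Pointwise conv to head_width -> global average pool -> linear."""

    def __init__(self, cin: int, head_width: int, num_classes: int,
                 *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.reduce = Conv2d(cin, head_width, 1, bias=True, rng=rng)
        self.act = ReLU()
        self.pool = GlobalAvgPool()
        self.fc = Linear(head_width, num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.pool(self.act(self.reduce(x))))


class MultiExitModel(Module):
    """Backbone plus three auxiliary exit heads (stages 1-3) and the final
    classifier (stage 4)."""

    def __init__(self, backbone: Backbone, head_width: int = DEFAULT_HEAD_WIDTH,
                 num_classes: int | None = None,
                 *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if not getattr(backbone, "tap_channels", None):
            raise ValueError("backbone exposes no tap points")
        self.backbone = backbone
        self.num_classes = num_classes or backbone.cfg.num_classes
        self.heads = [ExitHead(c, head_width, self.num_classes, rng=rng)
                      for c in backbone.tap_channels]
        self.stage_eval_count = 0   # counts stage evaluations (see dynamic_inference)

    @property
    def n_stages(self) -> int:
        return len(self.heads) + 1

    def forward(self, x: Tensor) -> list[Tensor]:
        """All-stage forward: returns [z1, z2, z3, z_final] logits."""
        taps, feat = self.backbone.forward_features(x)
        outs = [head(t) for head, t in zip(self.heads, taps)]
        outs.append(self.backbone.classifier(feat))
        return outs

    def final_logits(self, x: Tensor) -> Tensor:
        """Plain final-head forward pass (no early exits evaluated)."""
        _, feat = self.backbone.forward_features(x)
        return self.backbone.classifier(feat)

    def iter_stage_logits(self, x: Tensor):
        """Lazily yield per-stage logits, computing the trunk incrementally."""
        h = self.backbone.layer2(self.backbone.layer1(self.backbone.stem(x)))
        for i, stage in enumerate(self.backbone.vit_stages):
            h = stage(h)
            self.stage_eval_count += 1
            yield self.heads[i](h)
        self.stage_eval_count += 1
        yield self.backbone.classifier(self.backbone.pool(h))


def attach_exit_heads(backbone: Backbone, head_width: int = DEFAULT_HEAD_WIDTH,
                      num_classes: int | None = None, seed: int = 0) -> MultiExitModel:
    return MultiExitModel(backbone, head_width, num_classes,
                          rng=np.random.default_rng(seed))


@dataclass
class JointLossReport:
    stage_losses: list[Tensor]
    weights: tuple[float, ...]
    total: Tensor

    def values(self) -> list[float]:
        return [float(l.data) for l in self.stage_losses]


def joint_loss(stage_logits: list[Tensor], labels: np.ndarray,
               weights: tuple[float, ...] | None = None) -> JointLossReport:
    """Per-stage cross-entropy, combined as total = sum_i w_i * L_i.

    By default every stage (the three auxiliary heads and the final
    classifier) contributes with unit weight.
    """
    if weights is None:
        weights = (1.0,) * len(stage_logits)
    if len(weights) != len(stage_logits):
        raise ValueError("one weight per stage required")
    losses = [ag.cross_entropy(z, labels) for z in stage_logits]
    total = losses[0] * weights[0]
    for w, l in zip(weights[1:], losses[1:]):
        total = ag.add(total, l * w)
    return JointLossReport(losses, tuple(weights), total)


def dynamic_inference(x: Tensor | np.ndarray, model: MultiExitModel,
                      policy: ExitPolicy) -> list[StagePrediction]:
    """Run the threshold-gated cascade on a batch.

    Stages are evaluated in order; once every sample in the batch has exited,
    later stages are not computed at all, and stages are only evaluated on
    the samples still in flight (``model.stage_eval_count`` counts stage
    evaluations, so a never-exiting policy can be distinguished from an
    always-exit-at-1 policy).
    """
    if policy.n_stages != model.n_stages:
        raise ValueError(f"policy has {policy.n_stages} stages, "
                         f"model has {model.n_stages}")
    x = x if isinstance(x, Tensor) else Tensor(x)
    n = x.shape[0]
    results: list[StagePrediction | None] = [None] * n

    with ag.no_grad():
        h = model.backbone.layer2(model.backbone.layer1(model.backbone.stem(x)))
        alive = np.arange(n)
        for si in range(model.n_stages):
            final = si == model.n_stages - 1
            if final:
                logits = model.backbone.classifier(
                    model.backbone.pool(h)).data
            else:
                h = model.backbone.vit_stages[si](h)
                logits = model.heads[si](h).data
            model.stage_eval_count += 1
            keep = []
            for row, sample_i in enumerate(alive):
                pred = StagePrediction.from_logits(si + 1, logits[row])
                if policy.passes(pred):
                    results[sample_i] = pred
                else:
                    keep.append(row)
            if not keep:
                break
            alive = alive[keep]
            h = Tensor(h.data[keep])
    return results  # type: ignore[return-value]


def exit_statistics(predictions: list[StagePrediction],
                    n_stages: int | None = None) -> dict:
    """Per-stage exit fractions (sum to 1) and the mean exit stage index."""
    if not predictions:
        raise ValueError("no predictions")
    n_stages = n_stages or max(p.stage_index for p in predictions)
    counts = np.zeros(n_stages)
    for p in predictions:
        counts[p.stage_index - 1] += 1
    fractions = counts / counts.sum()
    mean_stage = float(sum(p.stage_index for p in predictions) / len(predictions))
    return {"fractions": fractions, "mean_stage": mean_stage,
            "counts": counts.astype(int)}
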
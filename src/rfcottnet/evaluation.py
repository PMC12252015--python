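"""Confusion-matrix metrics and the model profiler (params / MACs / storage).

Metrics: per-class precision tp/(tp+fp), recall tp/(tp+fn), F1 = 2PR/(P+R);
aggregated accuracy = trace/total.  Macro averages are unweighted class means
(the convention matching distinct printed precision/recall values); micro
averages are also emitted, for which precision = recall = accuracy in
single-label multiclass classification.

The profiler counts multiply-accumulates (one MAC = one FLOP here),
convention: conv k^2*cin*cout*Hout*Wout / groups, linear din*dout, separable
attention 3kd + 3kd^2 per token group; normalization and activations excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.modules import MacRecorder, Module, NORM_TYPES
from .models.multi_exit import MultiExitModel


@dataclass
class ConfusionCounts:
    """C x C confusion matrix (rows = true class) and one-vs-rest counts."""

    matrix: np.ndarray
    classes: tuple[str, ...] | None = None

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def tp(self, c: int) -> int:
        return int(self.matrix[c, c])

    def fp(self, c: int) -> int:
        return int(self.matrix[:, c].sum() - self.matrix[c, c])

    def fn(self, c: int) -> int:
        return int(self.matrix[c, :].sum() - self.matrix[c, c])

    def tn(self, c: int) -> int:
        return self.total - self.tp(c) - self.fp(c) - self.fn(c)


def confusion_matrix(y_true, y_pred, n_classes: int,
                     classes: tuple[str, ...] | None = None) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    if len(y_true) and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError("label outside [0, n_classes)")
    mat = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionCounts(mat.astype(np.int64), classes)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    binary_accuracy: float   # one-vs-rest (tp+tn)/total


@dataclass
class MetricsReport:
    """All values as percentages in [0, 100]."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "macro_precision", "macro_recall", "macro_f1",
              "micro_precision", "micro_recall", "micro_f1")}
        d["per_class"] = {k: vars(v) for k, v in self.per_class.items()}
        return d


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, on the percentage scale."""
    if precision_pct == recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def metrics_from_confusion(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    C = counts.n_classes
    per_class = {}
    precs, recs, f1s = [], [], []
    for c in range(C):
        tp, fp, fn, tn = counts.tp(c), counts.fp(c), counts.fn(c), counts.tn(c)
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        name = counts.classes[c] if counts.classes else str(c)
        per_class[name] = ClassMetrics(p, r, f1_score(p, r), tp + fn,
                                       100.0 * (tp + tn) / counts.total)
        precs.append(p)
        recs.append(r)
        f1s.append(f1_score(p, r))
    accuracy = 100.0 * np.trace(counts.matrix) / counts.total
    tp_sum = sum(counts.tp(c) for c in range(C))
    fp_sum = sum(counts.fp(c) for c in range(C))
    fn_sum = sum(counts.fn(c) for c in range(C))
    micro_p = 100.0 * tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
    micro_r = 100.0 * tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
    return MetricsReport(accuracy, float(np.mean(precs)), float(np.mean(recs)),
                         float(np.mean(f1s)), micro_p, micro_r,
                         f1_score(micro_p, micro_r), per_class)


# ---------------------------------------------------------------------------
# profiler
# ---------------------------------------------------------------------------

@dataclass
class ModelProfile:
    param_count: int
    param_count_no_norm: int
    flop_count: int                       # full-path MACs, one input image
    stage_cumulative_flops: list[int]     # cost up to each exit (incl. head)
    storage_bytes: int | None = None

    @property
    def params_millions(self) -> float:
        return round(self.param_count / 1e6, 1)

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["params_millions"] = self.params_millions
        return d


def count_params(model: Module) -> tuple[int, int]:
    """(total trainable params, total excluding normalization layers)."""
    total = model.num_parameters()
    norm = 0
    for _, mod in model.named_modules():
        if isinstance(mod, NORM_TYPES):
            norm += mod.gamma.size + mod.beta.size
    return total, total - norm


def count_flops(model: Module, input_shape: tuple[int, ...]) -> tuple[int, list]:
    """Full-path MAC count for one input of ``input_shape`` (C, H, W)."""
    x = Tensor(np.zeros((1,) + tuple(input_shape), dtype=np.float32))
    was_training = model.training
    model.eval()
    with MacRecorder() as rec, ag.no_grad():
        model(x)
    model.train(was_training)
    return rec.total, list(rec.entries)


def _segment_macs(fn) -> tuple[int, object]:
    with MacRecorder() as rec, ag.no_grad():
        out = fn()
    return rec.total, out


def profile_model(model: MultiExitModel, input_hw: int | None = None,
                  storage_bytes: int | None = None) -> ModelProfile:
    """Parameter, MAC and per-exit cumulative MAC profile of a multi-exit model."""
    hw = input_hw or model.backbone.cfg.image_size
    x = Tensor(np.zeros((1, 3, hw, hw), dtype=np.float32))
    was_training = model.training
    model.eval()
    bb = model.backbone
    base, h = _segment_macs(lambda: bb.layer2(bb.layer1(bb.stem(x))))
    # cascade accounting: a sample exiting at stage i has evaluated the trunk
    # up to stage i and every head 1..i, so cumulative cost is monotone
    cumulative = []
    running = base
    for i, stage in enumerate(bb.vit_stages):
        s_cost, h = _segment_macs(lambda: stage(h))
        h_cost, _ = _segment_macs(lambda: model.heads[i](h))
        running += s_cost + h_cost
        cumulative.append(running)
    f_cost, _ = _segment_macs(lambda: bb.classifier(bb.pool(h)))
    cumulative.append(running + f_cost)
    model.train(was_training)
    total, no_norm = count_params(model)
    return ModelProfile(total, no_norm, cumulative[-1], cumulative,
                        storage_bytes)


def expected_inference_cost(exit_fractions, cumulative_flops) -> float:
    """Expected MACs per sample under given exit fractions.

    Fractions must form a simplex; cumulative stage costs must be
    non-decreasing, so the expectation never exceeds the full-path cost.
    """
    f = np.asarray(exit_fractions, dtype=np.float64)
    c = np.asarray(cumulative_flops, dtype=np.float64)
    if f.shape != c.shape:
        raise ValueError("fractions and costs differ in length")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("exit fractions must form a probability simplex")
    if np.any(np.diff(c) < 0):
        raise ValueError("cumulative stage costs must be non-decreasing")
    return float(f @ c)
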
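"""INT8 quantization-aware training and export.

The five-step workflow: (1) FP32 baseline, (2) insertion of fake-quantization
nodes on weights and activations, (3) fine-tuning with the nodes in place
(straight-through gradients), (4) freezing and retaining per-layer scale /
zero-point, (5) export of the INT8 model.

Scheme: symmetric per-output-channel INT8 for weights (codes in [-127, 127]),
asymmetric per-tensor INT8 for activations (codes in [-128, 127]) with
EMA min/max range observers, round-half-to-even.  Biases and normalization
parameters are cast to half precision at freeze time so the exported file
reproduces the frozen fake-quant forward pass bit-exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.modules import (BatchNorm2d, Conv2d, LayerNorm, Linear, MacRecorder,
                         Module, Parameter)
from .models.attention import SeparableSelfAttention
from .models.backbone import BackboneConfig, MobileViTStage, build_backbone
from .models.multi_exit import MultiExitModel, attach_exit_heads


@dataclass
class QuantSpec:
    """Bitwidth and schemes of the INT8 recipe (all fields overridable)."""

    bitwidth: int = 8
    weight_scheme: str = "symmetric_per_channel"
    activation_scheme: str = "asymmetric_per_tensor"
    ema_momentum: float = 0.99
    rounding: str = "half_to_even"
    scale: float | np.ndarray | None = None   # for direct quantize_tensor use
    zero_point: int | np.ndarray = 0

    @property
    def qmin(self) -> int:
        return -(2 ** (self.bitwidth - 1))

    @property
    def qmax(self) -> int:
        return 2 ** (self.bitwidth - 1) - 1

    @property
    def weight_qmin(self) -> int:
        # symmetric: the most negative code is unused so the range is balanced
        return -self.qmax


def quantize_tensor(x: np.ndarray, spec: QuantSpec,
                    symmetric: bool | None = None) -> np.ndarray:
    """q = clamp(round(x / scale) + zero_point, qmin, qmax) as integers."""
    if spec.scale is None or np.any(np.asarray(spec.scale) <= 0):
        raise ValueError("spec.scale must be positive")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    qmin = spec.weight_qmin if symmetric else spec.qmin
    q = np.clip(np.round(x / spec.scale) + spec.zero_point, qmin, spec.qmax)
    return q.astype(np.int32 if spec.bitwidth > 8 else np.int8)


def dequantize_tensor(q: np.ndarray, spec: QuantSpec) -> np.ndarray:
    return ((q.astype(np.float32) - spec.zero_point) * spec.scale).astype(np.float32)


def weight_scales(w: np.ndarray, spec: QuantSpec) -> np.ndarray:
    """Per-output-channel symmetric scales (axis 0 = output channel).

    Scales are rounded to half precision so the serialized model (which
    stores them as float16) reproduces the fake-quant forward bit-exactly.
    """
    flat = np.abs(w.reshape(w.shape[0], -1))
    amax = flat.max(axis=1)
    scale = np.maximum(amax / spec.qmax, 1e-12)
    if spec.bitwidth <= 8:  # INT8 storage keeps scales in half precision
        scale = np.maximum(scale, 1e-7).astype(np.float16)
    return scale.astype(np.float32)


def matrix_scales(w: np.ndarray, spec: QuantSpec) -> np.ndarray:
    """Per-output-column symmetric scales for (din, dout) matrices."""
    scale = np.maximum(np.abs(w).max(axis=0) / spec.qmax, 1e-12)
    if spec.bitwidth <= 8:
        scale = np.maximum(scale, 1e-7).astype(np.float16)
    return scale.astype(np.float32)


class ActivationObserver(Module):
    """EMA min/max range observer for per-tensor asymmetric quantization."""

    def __init__(self, spec: QuantSpec):
        super().__init__()
        self.spec = spec
        self.running_range = np.array([0.0, 0.0], dtype=np.float32)
        self.initialized = False
        self.frozen = False

    def observe(self, x: np.ndarray) -> None:
        lo, hi = float(x.min()), float(x.max())
        if not self.initialized:
            self.running_range[:] = (lo, hi)
            self.initialized = True
        else:
            m = self.spec.ema_momentum
            self.running_range[0] = m * self.running_range[0] + (1 - m) * lo
            self.running_range[1] = m * self.running_range[1] + (1 - m) * hi

    def qparams(self) -> tuple[float, int]:
        lo = min(float(self.running_range[0]), 0.0)
        hi = max(float(self.running_range[1]), 0.0)
        scale = max((hi - lo) / (self.spec.qmax - self.spec.qmin), 1e-12)
        zp = int(np.clip(np.round(self.spec.qmin - lo / scale),
                         self.spec.qmin, self.spec.qmax))
        return scale, zp

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.frozen:
            self.observe(x.data)
        if not self.initialized:
            return x
        scale, zp = self.qparams()
        return ag.fake_quantize(x, np.float32(scale), np.int32(zp),
                                self.spec.qmin, self.spec.qmax)


def _fake_quant_weight(w: Parameter, spec: QuantSpec) -> Tensor:
    scales = weight_scales(w.data, spec)
    shape = (w.data.shape[0],) + (1,) * (w.data.ndim - 1)
    return ag.fake_quantize(w, scales.reshape(shape), np.int32(0),
                            spec.weight_qmin, spec.qmax)


def _fake_quant_matrix(w: Parameter, spec: QuantSpec) -> Tensor:
    """Per-output-column symmetric fake quantization for (din, dout) mats."""
    return ag.fake_quantize(w, matrix_scales(w.data, spec), np.int32(0),
                            spec.weight_qmin, spec.qmax)


class QuantConv2d(Module):
    def __init__(self, inner: Conv2d, spec: QuantSpec):
        super().__init__()
        self.inner = inner
        self.spec = spec
        self.observer = ActivationObserver(spec)

    def forward(self, x: Tensor) -> Tensor:
        wq = _fake_quant_weight(self.inner.weight, self.spec)
        out = ag.conv2d(x, wq, self.inner.bias, stride=self.inner.stride,
                        padding=self.inner.padding, groups=self.inner.groups)
        _, _, ho, wo = out.shape
        MacRecorder.record("conv2d", self.inner.kernel_size ** 2 *
                           (self.inner.in_channels // self.inner.groups) *
                           self.inner.out_channels * ho * wo)
        return self.observer(out)


class QuantLinear(Module):
    def __init__(self, inner: Linear, spec: QuantSpec):
        super().__init__()
        self.inner = inner
        self.spec = spec
        self.observer = ActivationObserver(spec)

    def forward(self, x: Tensor) -> Tensor:
        wq = _fake_quant_matrix(self.inner.weight, self.spec)
        out = ag.matmul(x, wq)
        if self.inner.bias is not None:
            out = ag.add(out, self.inner.bias)
        MacRecorder.record("linear", self.inner.in_features * self.inner.out_features)
        return self.observer(out)


class QuantAttention(Module):
    """Separable attention with fake-quantized projections and gated output."""

    def __init__(self, inner: SeparableSelfAttention, spec: QuantSpec):
        super().__init__()
        self.inner = inner
        self.spec = spec
        self.observer = ActivationObserver(spec)

    def forward(self, x: Tensor) -> Tensor:
        m, spec = self.inner, self.spec
        d = m.dim
        k_axis = x.ndim - 2
        k = x.shape[k_axis]
        groups = int(np.prod(x.shape[:k_axis])) if k_axis else 1
        wi = _fake_quant_matrix(m.w_i, spec)
        wk = _fake_quant_matrix(m.w_k, spec)
        wv = _fake_quant_matrix(m.w_v, spec)
        wo = _fake_quant_matrix(m.w_o, spec)
        cs = ag.softmax(ag.matmul(x, wi), axis=k_axis)
        cv = ag.sum_(ag.mul(cs, ag.add(ag.matmul(x, wk), m.b_k)),
                     axis=k_axis, keepdims=True)
        xv = ag.relu(ag.add(ag.matmul(x, wv), m.b_v))
        y = ag.add(ag.matmul(ag.mul(cv, xv), wo), m.b_o)
        MacRecorder.record("separable_attention", groups * (3 * k * d + 3 * k * d * d))
        return self.observer(y)


_WRAP = {Conv2d: QuantConv2d, Linear: QuantLinear,
         SeparableSelfAttention: QuantAttention}
_QUANT_TYPES = (QuantConv2d, QuantLinear, QuantAttention)


def insert_fake_quant(model: Module, spec: QuantSpec | None = None) -> Module:
    """Wrap every conv/linear/attention layer with fake-quantization in place.

    Parameters are shared with the original modules, so optimizer state and
    checkpoints carry over.  Returns the (mutated) model.
    """
    spec = spec or QuantSpec()
    for _, mod in list(model.named_modules()):
        for name, attr in list(vars(mod).items()):
            if type(attr) in _WRAP:
                setattr(mod, name, _WRAP[type(attr)](attr, spec))
            elif isinstance(attr, list):
                for i, item in enumerate(attr):
                    if type(item) in _WRAP:
                        attr[i] = _WRAP[type(item)](item, spec)
    return model


def iter_quant_modules(model: Module):
    for name, mod in model.named_modules():
        if isinstance(mod, _QUANT_TYPES):
            yield name, mod


def is_quantized(model: Module) -> bool:
    return any(True for _ in iter_quant_modules(model))


def calibrate(model: Module, x: np.ndarray | Tensor) -> None:
    """One observation pass: initializes observers to the batch min/max."""
    model.train()
    with ag.no_grad():
        model(x if isinstance(x, Tensor) else Tensor(x))
    model.eval()


def freeze_quantization(model: Module) -> None:
    """Freeze observers and cast non-weight parameters to half precision.

    After freezing, two evaluations of the model are bit-identical and the
    INT8 export round-trips exactly.
    """
    any_obs = False
    for _, mod in iter_quant_modules(model):
        mod.observer.frozen = True
        any_obs = any_obs or mod.observer.initialized
    if not any_obs:
        raise RuntimeError("no initialized observers: run calibration or "
                           "fine-tuning before freezing")
    for _, mod in model.named_modules():
        if isinstance(mod, (BatchNorm2d, LayerNorm)):
            for p in (mod.gamma, mod.beta):
                p.data = p.data.astype(np.float16).astype(np.float32)
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = mod.running_mean.astype(np.float16).astype(np.float32)
                mod.running_var = mod.running_var.astype(np.float16).astype(np.float32)
        if isinstance(mod, _QUANT_TYPES):
            inner = mod.inner
            bias_params = [inner.bias] if getattr(inner, "bias", None) is not None else []
            if isinstance(inner, SeparableSelfAttention):
                bias_params = [inner.b_k, inner.b_v, inner.b_o]
            for p in bias_params:
                p.data = p.data.astype(np.float16).astype(np.float32)


def is_frozen(model: Module) -> bool:
    mods = list(iter_quant_modules(model))
    return bool(mods) and all(m.observer.frozen for _, m in mods)


def qat_finetune(model: Module, images: np.ndarray, labels: np.ndarray,
                 epochs: int = 1, seed: int = 0, lr: float = 1e-4,
                 batch_size: int = 32,
                 stage_weights: tuple[float, ...] | None = None):
    """Fine-tune a fake-quantized model, then freeze ranges.

    Observers track activation ranges by EMA during the fine-tune; at the end
    every quantized layer retains its frozen (scale, zero_point).
    """
    from .training import train_model  # local import to avoid a cycle

    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not is_quantized(model):
        raise ValueError("model has no fake-quantization nodes")
    history = train_model(model, images, labels, epochs=epochs, seed=seed,
                          lr=lr, batch_size=batch_size,
                          stage_weights=stage_weights)
    freeze_quantization(model)
    return history


# ---------------------------------------------------------------------------
# INT8 serialization
# ---------------------------------------------------------------------------

@dataclass
class SizeReport:
    params: int
    bytes: int

    @property
    def mb(self) -> float:
        return self.bytes / 1024 ** 2

    def to_dict(self) -> dict:
        return {"params": self.params, "bytes": self.bytes, "mb": self.mb}


def _weight_entries(model: MultiExitModel):
    """Yield (key, parameter, is_matrix) for every quantizable weight."""
    for name, mod in iter_quant_modules(model):
        if isinstance(mod, QuantConv2d):
            yield f"{name}.inner.weight", mod.inner.weight, False
        elif isinstance(mod, QuantLinear):
            yield f"{name}.inner.weight", mod.inner.weight, True
        else:
            for wn in ("w_i", "w_k", "w_v", "w_o"):
                yield f"{name}.inner.{wn}", getattr(mod.inner, wn), True


def export_int8(model: MultiExitModel, path: str | os.PathLike,
                spec: QuantSpec | None = None, head_width: int | None = None) -> SizeReport:
    """Serialize the frozen model: one byte per weight plus per-layer
    scale/zero-point metadata.

    Container layout (npz archive): a packed int8 code buffer for all
    conv/linear/attention weights, a packed float16 buffer for scales,
    biases, norm parameters and batch-norm statistics, float32 observer
    ranges, and a zlib-compressed JSON index describing shapes and offsets.
    Loading reproduces the frozen fake-quant forward pass exactly.
    """
    import zlib

    spec = spec or QuantSpec()
    if not is_frozen(model):
        raise RuntimeError("quantization ranges are not frozen; "
                           "run qat_finetune or calibrate+freeze first")
    q_chunks: list[np.ndarray] = []
    s_chunks: list[np.ndarray] = []
    f_chunks: list[np.ndarray] = []
    index = {"weights": [], "others": [], "ranges": []}
    n_params = 0
    quant_keys = set()
    for key, p, is_matrix in _weight_entries(model):
        w = p.data
        if is_matrix:
            scales = matrix_scales(w, spec)
            sh = scales.shape
        else:
            scales = weight_scales(w, spec)
            sh = (w.shape[0],) + (1,) * (w.ndim - 1)
        # float64 division mirrors the fake-quant node exactly (tie behavior)
        q = np.clip(np.round(w.astype(np.float64) / scales.reshape(sh)),
                    spec.weight_qmin, spec.qmax)
        q_chunks.append(q.astype(np.int8).ravel())
        s_chunks.append(scales.astype(np.float16))
        index["weights"].append([key, list(w.shape), int(is_matrix)])
        quant_keys.add(key)
        n_params += w.size
    ranges = []
    for name, mod in iter_quant_modules(model):
        ranges.append(mod.observer.running_range.astype(np.float32))
        index["ranges"].append(name)
    # everything else (biases, norms, running statistics) in half precision
    for key, value in model.state_dict().items():
        if key in quant_keys:
            continue
        f_chunks.append(value.astype(np.float16).ravel())
        index["others"].append([key, list(value.shape)])
        if ".running_" not in key:
            n_params += value.size  # buffers are stored but not counted

    cfg = model.backbone.cfg
    meta = {
        "config": _config_dict(cfg),
        "head_width": head_width or getattr(model.heads[0].reduce, "inner",
                                            model.heads[0].reduce).out_channels,
        "num_classes": model.num_classes,
        "spec": {k: v for k, v in asdict(spec).items()
                 if k not in ("scale", "zero_point")},
        "index": index,
    }
    blob = zlib.compress(json.dumps(meta).encode(), 9)
    np.savez(os.fspath(path),
             codes=np.concatenate(q_chunks),
             scales=np.concatenate(s_chunks),
             others=np.concatenate(f_chunks) if f_chunks else np.zeros(0, np.float16),
             ranges=np.stack(ranges) if ranges else np.zeros((0, 2), np.float32),
             meta=np.frombuffer(blob, dtype=np.uint8))
    return SizeReport(params=n_params, bytes=os.path.getsize(path))


def _config_dict(cfg: BackboneConfig) -> dict:
    d = asdict(cfg)
    d["mobilevit_stages"] = [list(asdict(s).values()) for s in cfg.mobilevit_stages]
    return d


def _config_from_dict(d: dict) -> BackboneConfig:
    d = dict(d)
    d["mobilevit_stages"] = tuple(MobileViTStage(*s) for s in d["mobilevit_stages"])
    d["mv2_channels"] = tuple(d["mv2_channels"])
    return BackboneConfig(**d)


def load_int8(path: str | os.PathLike) -> MultiExitModel:
    """Rebuild the model from an INT8 export; forward pass reproduces the
    frozen fake-quant model exactly."""
    import zlib

    with np.load(os.fspath(path)) as z:
        codes, scales_buf = z["codes"], z["scales"]
        others, ranges = z["others"], z["ranges"]
        meta = json.loads(zlib.decompress(bytes(z["meta"])).decode())
    cfg = _config_from_dict(meta["config"])
    spec = QuantSpec(**meta["spec"])
    backbone = build_backbone(cfg, seed=0)
    model = attach_exit_heads(backbone, head_width=meta["head_width"],
                              num_classes=meta["num_classes"], seed=0)
    insert_fake_quant(model, spec)
    params = dict(model.named_parameters())

    q_off = s_off = 0
    for key, shape, is_matrix in meta["index"]["weights"]:
        size = int(np.prod(shape))
        q = codes[q_off:q_off + size].reshape(shape)
        n_scales = shape[-1] if is_matrix else shape[0]
        sc = scales_buf[s_off:s_off + n_scales].astype(np.float32)
        sh = shape[-1:] if is_matrix else ([shape[0]] + [1] * (len(shape) - 1))
        params[key].data = (q.astype(np.float32) * sc.reshape(sh)).astype(np.float32)
        q_off += size
        s_off += n_scales
    f_off = 0
    for key, shape in meta["index"]["others"]:
        size = int(np.prod(shape))
        value = others[f_off:f_off + size].reshape(shape).astype(np.float32)
        f_off += size
        if key in params:
            params[key].data = value
        else:  # running buffer (e.g. batch-norm statistics)
            obj = model
            *parts, leaf = key.split(".")
            for part in parts:
                obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
            setattr(obj, leaf, value)
    quant_mods = dict(iter_quant_modules(model))
    for row, name in zip(ranges, meta["index"]["ranges"]):
        obs = quant_mods[name].observer
        obs.running_range = row.astype(np.float32)
        obs.initialized = True
        obs.frozen = True
    model.eval()
    return model
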
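"""YAML run configuration: one serializable object driving every command."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .models.backbone import BackboneConfig, MobileViTStage
from .models.multi_exit import DEFAULT_HEAD_WIDTH


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 5e-5
    optimizer: str = "adamw"
    epochs: int = 10
    weight_decay: float = 0.01
    stage_weights: list[float] | None = None


@dataclass
class ExitConfig:
    mode: str = "confidence"
    thresholds: list[float] = field(default_factory=lambda: [0.6, 0.7, 0.8])


@dataclass
class QuantConfig:
    bitwidth: int = 8
    epochs: int = 1
    learning_rate: float = 1e-4


@dataclass
class DataConfig:
    root: str = "data"
    image_size: int = 256
    images_per_class: int = 30
    train_fraction: float = 0.8
    image_format: str = "png"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/latest"
    data: DataConfig = field(default_factory=DataConfig)
    model: BackboneConfig = field(default_factory=BackboneConfig)
    head_width: int = DEFAULT_HEAD_WIDTH
    train: TrainConfig = field(default_factory=TrainConfig)
    exit: ExitConfig = field(default_factory=ExitConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["mobilevit_stages"] = [
            list(asdict(s).values()) for s in self.model.mobilevit_stages]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def dump(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def desk_preset() -> RunConfig:
    """Desk-scale preset: width/8 model on 64 x 64 synthetic images."""
    cfg = RunConfig()
    cfg.model = BackboneConfig(width_multiplier=0.125, image_size=64)
    cfg.head_width = 48
    cfg.data.image_size = 64
    cfg.train = TrainConfig(batch_size=32, learning_rate=5e-3, epochs=30)
    return cfg


def load_config(path: str | os.PathLike | None) -> RunConfig:
    if path is None:
        return desk_preset()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = desk_preset() if raw.pop("preset", "desk") == "desk" else RunConfig()
    for key in ("seed", "out_dir", "head_width"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "model" in raw:
        m = dict(raw["model"])
        base = asdict(cfg.model)
        base.pop("mobilevit_stages")
        stages = m.pop("mobilevit_stages", None)
        kwargs = {**base, **m}
        if stages is not None:
            kwargs["mobilevit_stages"] = tuple(MobileViTStage(*s) for s in stages)
        else:
            kwargs["mobilevit_stages"] = cfg.model.mobilevit_stages
        cfg.model = BackboneConfig(**kwargs)
    for key, cls in (("data", DataConfig), ("train", TrainConfig),
                     ("exit", ExitConfig), ("quant", QuantConfig)):
        if key in raw:
            setattr(cfg, key, cls(**{**asdict(getattr(cfg, key)), **raw[key]}))
    return cfg
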
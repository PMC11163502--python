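"""YAML configuration round trip for model, training and loss settings."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .losses import LossConfig
from .model import ModelConfig, preset
from .training import TrainConfig

__all__ = ["load_config", "save_config"]


def _filter(cls, d):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def load_config(path) -> tuple:
    """Read a YAML file with optional `model`, `train` and `loss` sections.

    The model section may specify ``ablation: 1..6`` (preset, optionally
    narrowed by ``base_channels``) or explicit ModelConfig fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    msec = dict(raw.get("model", {}))
    if "ablation" in msec:
        model_cfg = preset(int(msec.pop("ablation")),
                           base_channels=msec.pop("base_channels", None))
        if msec:
            raise ValueError(
                f"ablation presets are fixed; unexpected keys {sorted(msec)}")
    else:
        if "s3d_levels" in msec:
            msec["s3d_levels"] = frozenset(msec["s3d_levels"])
        for tup in ("down_convs", "up_convs", "enc_convs", "dec_convs",
                    "racm_levels"):
            if tup in msec:
                msec[tup] = tuple(msec[tup])
        model_cfg = _filter(ModelConfig, msec)
    loss_cfg = _filter(LossConfig, dict(raw.get("loss", {})))
    tsec = dict(raw.get("train", {}))
    tsec.pop("loss", None)
    train_cfg = _filter(TrainConfig, {**tsec, "loss": loss_cfg})
    return model_cfg, train_cfg, loss_cfg


def save_config(model_cfg: ModelConfig, train_cfg: TrainConfig, path) -> None:
    d = {"model": asdict(model_cfg), "train": asdict(train_cfg)}
    d["model"]["s3d_levels"] = sorted(d["model"]["s3d_levels"])
    d["loss"] = d["train"].pop("loss")
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
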
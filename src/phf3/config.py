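"""Run configuration: a flat, YAML-serializable record of every knob the
training engine consumes, with the two built-in model presets.

``paper``: the full-size model (stage dims 64/128/320/512, depths 3/8/27/3,
ResNet50 plan, 224-pixel crops, batch 128, SGD lr 1e-3 ×0.1 every 10 of 50
epochs) — the published training protocol; forward-pass shape checks run on
CPU, full training of this preset does not.

``tiny``: a desk-scale preset (dims 16/32/64/128, one block per stage, CNN
plan 32/64/128/256, 64-pixel crops, channel-reduced covariance head) for
training end-to-end on a single CPU. Its optimizer settings are chosen for
training from random initialization — the full protocol assumes pretrained
branches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .data import IMAGENET_MEAN, IMAGENET_STD, AugmentSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    preset: str = "tiny"
    num_classes: int = 4
    # optimization
    epochs: int = 30
    batch_size: int = 16
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-5
    lr_decay: float = 0.1
    lr_step: int = 10
    # objective
    loss_weights: tuple = (1.0, 1.0, 2.0)
    label_smoothing: float = 0.1
    # architecture switches
    sop_iterations: int = 8
    sop_reduce_channels: int = 64
    sop_mode: str = "sop"
    ffm_enabled: bool = True
    # preprocessing
    resize: int = 72
    crop: int = 64
    flip_p: float = 0.3
    clahe_enabled: bool = True
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    norm_mean: tuple = IMAGENET_MEAN
    norm_std: tuple = IMAGENET_STD
    # bookkeeping
    seed: int = 0
    deterministic: bool = True  # execution is deterministic throughout; flag
    #                             reserved for future non-deterministic kernels

    @classmethod
    def tiny(cls, **overrides) -> "RunConfig":
        return cls(**overrides)

    @classmethod
    def paper(cls, **overrides) -> "RunConfig":
        defaults = dict(
            preset="paper", epochs=50, batch_size=128, lr=1e-3,
            sop_reduce_channels=0, resize=256, crop=224,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def augment_spec(self) -> AugmentSpec:
        return AugmentSpec(
            flip_p=self.flip_p, resize=self.resize, crop=self.crop,
            clahe_enabled=self.clahe_enabled, clahe_clip=self.clahe_clip,
            clahe_tiles=self.clahe_tiles,
            mean=tuple(self.norm_mean), std=tuple(self.norm_std),
        )

    # -- YAML round trip ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loss_weights"] = list(self.loss_weights)
        d["norm_mean"] = list(self.norm_mean)
        d["norm_std"] = list(self.norm_std)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("loss_weights", "norm_mean", "norm_std"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
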
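"""Run configuration: one serializable bundle of every setting a
command needs, with lossless YAML/JSON round-trip.

Precedence when the CLI assembles a RunConfig: command-line flags
override file values, which override the published defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .entropy import EntropySpec
from .model import ModelConfig
from .preprocess import AugmentConfig
from .train import TrainConfig


@dataclass
class RunConfig:
    task: str = "A-B-C-D-E"
    data_root: str | None = None
    output_dir: str = "runs"
    k: int = 10
    seed: int = 0
    window: int = 512
    group_by_record: bool = False
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def to_dict(self) -> dict:
        return {
            "task": self.task, "data_root": self.data_root,
            "output_dir": self.output_dir, "k": self.k, "seed": self.seed,
            "window": self.window, "group_by_record": self.group_by_record,
            "model": self.model.to_dict(), "train": self.train.to_dict(),
            "augment": {"alpha": self.augment.alpha,
                        "copies_per_original": self.augment.copies_per_original,
                        "seed": self.augment.seed},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "train" in d:
            d["train"] = TrainConfig.from_dict(d["train"])
        if "augment" in d:
            d["augment"] = AugmentConfig(**d["augment"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=2) \
            if path.suffix == ".json" else yaml.safe_dump(self.to_dict())
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = json.loads(path.read_text()) if path.suffix == ".json" \
            else yaml.safe_load(path.read_text())
        return cls.from_dict(data)

    def with_entropy_kind(self, kind: str) -> "RunConfig":
        spec = EntropySpec(kind=kind, eps=self.model.entropy_spec.eps,
                           n_bins=self.model.entropy_spec.n_bins,
                           order=self.model.entropy_spec.order)
        d = self.to_dict()
        d["model"]["entropy_spec"] = spec.to_dict()
        return RunConfig.from_dict(d)
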
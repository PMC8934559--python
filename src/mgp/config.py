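"""Run configuration: one YAML file drives every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import CueGains


@dataclass
class RunConfig:
    master_seed: int = 0
    # generator
    n_per_class: int = 60
    gains: CueGains = field(default_factory=CueGains)
    write_images: bool = True
    # observers
    n_observers: int = 10
    rating_noise_sd: float = 0.05
    lapse_rate: float = 0.0
    # features
    pca_cum_var: float = 0.99
    texture_scales: int = 3
    texture_orientations: int = 4
    texture_neighborhood: int = 5
    # training
    n_repeats: int = 2
    cnn_depth: int = 3
    cnn_max_epochs: int = 6
    # diagnostic pipeline (desk scale)
    diag_exp1_per_class: int = 1000
    diag_a1_per_class: int = 2000
    diag_a1_quota: int = 250
    diag_final_per_bin: int = 8
    # search
    search_depths: tuple = (1, 2, 3)
    search_iters: int = 4
    search_strategy: str = "surrogate"
    search_pool_per_class: int = 60
    # interpret
    noise_sigmas: tuple = (1e-3, 1e-2, 1e-1, 1.0)
    noise_reps: int = 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gains"] = asdict(self.gains)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gains" in d and isinstance(d["gains"], dict):
            d["gains"] = CueGains(**d["gains"])
        for key in ("search_depths", "noise_sigmas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
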
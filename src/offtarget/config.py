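"""Run configuration: one serialisable object covering every pipeline stage.

A :class:`RunConfig` nests per-stage parameter blocks (world generation,
featurisation, model, training, screening, evaluation), carries the master
seed, and round-trips through JSON.  Two presets are shipped: ``test``
(latent width 64, minutes on one CPU) and ``paper-shape`` (latent width
1024 and the published relative proportions: ~118 adverse-effect targets,
1000 control proteins, 6 screened compounds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

__all__ = ["RunConfig", "preset", "PRESETS"]


@dataclasses.dataclass
class WorldParams:
    n_compounds: int = 200
    n_targets: int = 100
    n_positive_per_target: int = 6
    motif_smiles_fragment: str = "OCCN"
    motif_sequence: str = "HKWWHE"
    ae_vocab_size: int = 40
    variant_rate: float = 0.2
    n_controls: int = 100
    null_world: bool = False


@dataclasses.dataclass
class FeaturizationParams:
    radius: int = 2
    n_bits: int = 2048
    k: int = 3
    dimension: int = 100
    frames: int = 3
    window: int = 5
    epochs: int = 3
    aggregate: str = "sum"


@dataclasses.dataclass
class ModelParams:
    p: int = 64
    hidden: list[int] | None = None
    attention_mode: str = "gate"
    n_tokens: int = 8
    eps: float = 1e-5


@dataclasses.dataclass
class TrainParams:
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 30
    finetune_epochs: int = 10
    margin: float = 1.0
    n_decoys: int = 50
    loss_mix: float = 0.5
    bidirectional: bool = True
    validation_fraction: float = 0.15


@dataclasses.dataclass
class ScreenParams:
    n_repetitions: int = 5
    max_compounds: int | None = None
    distance_space: str = "projected"  # or "latent" for diagnostics


@dataclasses.dataclass
class EvalParams:
    threshold_quantile: float = 0.05
    max_edit_fraction: float = 0.2


@dataclasses.dataclass
class RunConfig:
    """Every knob of a full simulate-to-evaluate run."""

    master_seed: int = 7
    preset_name: str = "test"
    world: WorldParams = dataclasses.field(default_factory=WorldParams)
    featurization: FeaturizationParams = dataclasses.field(default_factory=FeaturizationParams)
    model: ModelParams = dataclasses.field(default_factory=ModelParams)
    training: TrainParams = dataclasses.field(default_factory=TrainParams)
    screening: ScreenParams = dataclasses.field(default_factory=ScreenParams)
    evaluation: EvalParams = dataclasses.field(default_factory=EvalParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        kwargs = dict(payload)
        for name, sub in (
            ("world", WorldParams),
            ("featurization", FeaturizationParams),
            ("model", ModelParams),
            ("training", TrainParams),
            ("screening", ScreenParams),
            ("evaluation", EvalParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def preset(name: str, master_seed: int = 7) -> RunConfig:
    """Build one of the shipped configurations."""
    if name == "test":
        return RunConfig(master_seed=master_seed, preset_name="test")
    if name == "paper-shape":
        return RunConfig(
            master_seed=master_seed,
            preset_name="paper-shape",
            world=WorldParams(n_compounds=200, n_targets=236, n_controls=1000),
            model=ModelParams(p=1024),
            screening=ScreenParams(n_repetitions=5, max_compounds=6),
        )
    raise ValueError(f"unknown preset {name!r} (available: {sorted(PRESETS)})")


PRESETS = {"test", "paper-shape"}
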
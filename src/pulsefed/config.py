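"""Run configuration: one YAML file covering every pipeline stage.

Every defaulted field carries a provenance tag — ``reference`` for values
fixed by the reference federated protocol (client counts, sampling, loss
weights, architecture sizes) and ``package`` for engineering defaults
chosen here (simulator levels, optimizer settings, discriminator channel
widths).  ``dump_config`` writes the provenance as inline comments;
``load_config`` ignores comments, so dump -> load -> dump is a fixed
point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .federated import FedConfig
from .gan import DiscriminatorSpec, GeneratorSpec, LossWeights, TrainOptions
from .simulate import PerSegmentVariation, SimParams

__all__ = ["RunConfig", "load_config", "dump_config", "save_config"]

# dotted field name -> provenance
_PROVENANCE = {
    "sim": "package",
    "variation": "package",
    "gen.num_layers": "reference",
    "gen.hidden_units": "reference",
    "gen.input_len": "reference",
    "gen.output_len": "reference",
    "disc.input_len": "reference",
    "disc.channels": "package",
    "disc.kernel": "package",
    "loss.lambda_c": "reference",
    "loss.lambda_i": "reference",
    "fed.n_clients": "reference",
    "fed.clients_per_round": "reference",
    "fed.n_rounds": "reference",
    "fed.local_epochs": "reference",
    "fed.batch_size": "reference",
    "fed.seed": "package",
    "train.lr": "package",
    "train.beta1": "package",
    "train.beta2": "package",
    "calibration_s": "reference",
    "output_dir": "package",
    "seed": "package",
}


@dataclass
class RunConfig:
    """All knobs of the simulate -> train -> evaluate pipeline."""

    sim: SimParams = field(default_factory=SimParams)
    variation: PerSegmentVariation = field(default_factory=PerSegmentVariation)
    gen: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    loss: LossWeights = field(default_factory=LossWeights)
    fed: FedConfig = field(default_factory=FedConfig)
    train: TrainOptions = field(default_factory=TrainOptions)
    calibration_s: float = 60.0
    output_dir: str = "runs"
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one global seed to every seeded component."""
        return dataclasses.replace(
            self,
            seed=seed,
            sim=dataclasses.replace(self.sim, seed=seed),
            fed=dataclasses.replace(self.fed, seed=seed),
        )

    def validate(self) -> None:
        self.sim.validate()
        self.gen.validate()
        self.disc.validate()
        self.loss.validate()
        self.fed.validate()


_SECTIONS = {
    "sim": SimParams,
    "variation": PerSegmentVariation,
    "gen": GeneratorSpec,
    "disc": DiscriminatorSpec,
    "loss": LossWeights,
    "fed": FedConfig,
    "train": TrainOptions,
}


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; omitted fields keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if name == "disc" and "channels" in section:
            section["channels"] = tuple(section["channels"])
        kwargs[name] = cls(**section)
    for scalar in ("calibration_s", "output_dir", "seed"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _fmt(value) -> str:
    if isinstance(value, tuple):
        return "[" + ", ".join(map(str, value)) + "]"
    if isinstance(value, bool):
        return str(value).lower()
    return str(value)


def dump_config(cfg: RunConfig) -> str:
    """Serialize to YAML with a provenance comment on every field."""
    lines: list[str] = []
    for name in _SECTIONS:
        obj = dataclasses.asdict(cfg)[name]
        lines.append(f"{name}:")
        for key, value in obj.items():
            prov = _PROVENANCE.get(f"{name}.{key}", _PROVENANCE.get(name, "package"))
            lines.append(f"  {key}: {_fmt(value)}  # {prov}")
    for scalar in ("calibration_s", "output_dir", "seed"):
        prov = _PROVENANCE[scalar]
        lines.append(f"{scalar}: {_fmt(getattr(cfg, scalar))}  # {prov}")
    return "\n".join(lines) + "\n"


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(dump_config(cfg))
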
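"""Run configuration: nested YAML blocks mirroring each module's parameters.

A run config collects the reward, simulator, pipeline, agent, FQE and
analysis settings plus a single global seed. Unknown keys are rejected so a
typo cannot silently fall back to a default, and the resolved config is
serialized verbatim into every output directory for reproducibility.

The run-level defaults are desk-scale (small cohort, compact networks) so an
end-to-end run finishes on one CPU; the library dataclasses keep their own
publication-scale defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .agent import AgentConfig
from .ope import FQEConfig
from .rewards import RewardParams
from .simulator import SimConfig

__all__ = ["PipelineConfig", "AnalysisConfig", "RunConfig", "desk_scale_agent_config"]


@dataclass
class PipelineConfig:
    train_frac: float = 0.85
    missing_threshold: float = 0.30
    knn_k: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0.0 <= self.missing_threshold < 1.0:
            raise ValueError("missing_threshold must be in [0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class AnalysisConfig:
    delta_edges: tuple[float, ...] = (-10.0, -3.0, 3.0, 10.0)
    glucose_edges: tuple[float, ...] = (70.0, 100.0, 140.0, 180.0, 200.0, 250.0)
    n_bootstrap: int = 2000


def desk_scale_agent_config(**overrides) -> AgentConfig:
    """Compact-network agent settings for single-CPU runs."""
    base = dict(
        hidden_layers=(64, 64),
        batch_size=128,
        gradient_steps=5000,
        actor_lr=1e-3,
        critic_lr=1e-3,
        cql_alpha=1.0,
        n_ood_action_samples=8,
        n_actor_action_samples=2,
        quantile_embed_dim=32,
        return_sampling_temperature=2.0,
    )
    base.update(overrides)
    return AgentConfig(**base)


def _build(cls, block: dict, name: str):
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise TypeError(f"config block '{name}' must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise KeyError(f"unknown keys in config block '{name}': {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in block:
            continue
        v = block[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


@dataclass
class RunConfig:
    """End-to-end run settings; one seed governs every stage."""

    seed: int = 0
    output_dir: str = "runs/run0"
    log_level: str = "INFO"
    n_models: int = 3
    reward: RewardParams = field(default_factory=RewardParams)
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_patients=200))
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    agent: AgentConfig = field(default_factory=desk_scale_agent_config)
    fqe: FQEConfig = field(
        default_factory=lambda: FQEConfig(hidden_layers=(64, 64), lr=1e-3, gradient_steps=3000)
    )
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")

    _TOP_KEYS = ("seed", "output_dir", "log_level", "n_models")
    _BLOCKS = {
        "reward": RewardParams,
        "sim": SimConfig,
        "pipeline": PipelineConfig,
        "agent": AgentConfig,
        "fqe": FQEConfig,
        "analysis": AnalysisConfig,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        unknown = set(raw) - set(cls._TOP_KEYS) - set(cls._BLOCKS)
        if unknown:
            raise KeyError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {k: raw[k] for k in cls._TOP_KEYS if k in raw}
        for name, klass in cls._BLOCKS.items():
            if name == "agent" and name not in raw:
                continue  # keep desk-scale factory default
            if name in raw:
                kwargs[name] = _build(klass, raw[name], name)
        cfg = cls(**kwargs)
        # a single global seed governs every stage unless a block overrides it
        if "seed" not in (raw.get("sim") or {}):
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        if "seed" not in (raw.get("agent") or {}):
            cfg.agent = dataclasses.replace(cfg.agent, seed=cfg.seed)
        if "seed" not in (raw.get("fqe") or {}):
            cfg.fqe = dataclasses.replace(cfg.fqe, seed=cfg.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        def plain(obj):
            d = dataclasses.asdict(obj)
            for k, v in d.items():
                if isinstance(v, tuple):
                    d[k] = list(v)
            return d

        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "n_models": self.n_models,
            "reward": plain(self.reward),
            "sim": plain(self.sim),
            "pipeline": plain(self.pipeline),
            "agent": plain(self.agent),
            "fqe": plain(self.fqe),
            "analysis": plain(self.analysis),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
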
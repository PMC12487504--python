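"""Run configuration: one YAML/JSON file drives every pipeline stage.

A single global seed fans out to stage-specific child seeds by stable
derivation (``numpy.random.SeedSequence``), so individual stages can be
rerun in isolation and identical configs produce identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import CleaningRules
from .errors import ConfigError
from .hmm import HMMConfig

_STAGES = ("simulate", "score", "fit", "compare", "classify", "agreement")


@dataclass(frozen=True)
class PermutationSettings:
    n_permutations: int = 1000
    convention: str = "plain"  # "plain" | "smoothed"
    relax_max_iter: int | None = None  # EM cap inside permutations (None = same as fit)


@dataclass(frozen=True)
class SubgroupSettings:
    n_subgroups_high: int = 30
    size: int = 7
    design: str = "balanced"  # "balanced" | "imbalanced_3to1"
    n_iterations: int = 10


@dataclass(frozen=True)
class SimulateSettings:
    n_high: int = 30
    n_low: int = 10


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    hmm: HMMConfig = field(default_factory=HMMConfig)
    cleaning: CleaningRules = field(default_factory=CleaningRules)
    permutation: PermutationSettings = field(default_factory=PermutationSettings)
    subgroups: SubgroupSettings = field(default_factory=SubgroupSettings)
    simulate: SimulateSettings = field(default_factory=SimulateSettings)
    scorer: str = "lexicon"

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage child seed derived from the global seed."""
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        child = np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        return int(child.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hmm"]["init_means"] = list(d["hmm"]["init_means"])
        return d


def _build(section: str, cls, mapping: dict):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(f"{section}: unknown field(s) {sorted(unknown)}")
    if "init_means" in mapping:
        mapping = dict(mapping, init_means=tuple(mapping["init_means"]))
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def config_from_mapping(mapping: dict) -> RunConfig:
    mapping = dict(mapping or {})
    sections = {
        "hmm": HMMConfig,
        "cleaning": CleaningRules,
        "permutation": PermutationSettings,
        "subgroups": SubgroupSettings,
        "simulate": SimulateSettings,
    }
    kwargs = {}
    for name, cls in sections.items():
        sub = mapping.pop(name, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"{name}: must be a mapping")
        kwargs[name] = _build(name, cls, sub)
    seed = mapping.pop("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed: must be an integer, got {seed!r}")
    scorer = mapping.pop("scorer", "lexicon")
    if mapping:
        raise ConfigError(f"unknown top-level field(s) {sorted(mapping)}")
    return RunConfig(seed=seed, scorer=scorer, **kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON — valid YAML) config file."""
    text = Path(path).read_text()
    try:
        mapping = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_mapping(mapping)


def dump_config(config: RunConfig) -> str:
    return json.dumps(config.to_dict(), sort_keys=True)
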
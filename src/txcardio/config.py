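"""Run configuration: YAML schema, validation, and resolved-config dumps.

A run configuration gathers the pacing protocol, solver settings, insult
grids, Arrhythmic-Index weights, classifier thresholds, input paths and the
seed.  Configurations are validated strictly (unknown keys are rejected), and
every command writes its fully resolved configuration next to its outputs so
runs are reproducible from the artifacts alone.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import yaml

from .insults import InsultSpec
from .metrics import ClassifierConfig
from .model import PacingProtocol, SolverSettings

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def _build(cls, section: Dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid '{name}' section: {e}") from e


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    out_dir: str = "txcardio_out"
    expression: Optional[str] = None
    annotations: Optional[str] = None
    gene_map: Optional[str] = None
    seed: int = 0
    top_k: int = 10
    drugs: Optional[Tuple[str, ...]] = None
    cell_lines: Optional[Tuple[str, ...]] = None
    ai_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    log_level: str = "INFO"
    protocol: PacingProtocol = field(default_factory=PacingProtocol)
    solver: SolverSettings = field(default_factory=SolverSettings)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    insults: Tuple[InsultSpec, ...] = field(
        default_factory=InsultSpec.default_battery)
    synth: Dict = field(default_factory=dict)

    def __post_init__(self):
        if any(w < 0 for w in self.ai_weights):
            raise ConfigError("ai_weights must be non-negative")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")

    # -- (de)serialization ---------------------------------------------------

    _SIMPLE_KEYS = ("out_dir", "expression", "annotations", "gene_map", "seed",
                    "top_k", "drugs", "cell_lines", "ai_weights", "log_level",
                    "synth")

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        raw = dict(raw or {})
        known = set(cls._SIMPLE_KEYS) | {"protocol", "solver", "classifier",
                                         "insults"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs = {k: raw[k] for k in cls._SIMPLE_KEYS if k in raw}
        for tup_key in ("drugs", "cell_lines", "ai_weights"):
            if kwargs.get(tup_key) is not None:
                kwargs[tup_key] = tuple(kwargs[tup_key])
        if "protocol" in raw:
            kwargs["protocol"] = _build(PacingProtocol, raw["protocol"],
                                        "protocol")
        if "solver" in raw:
            kwargs["solver"] = _build(SolverSettings, raw["solver"], "solver")
        if "classifier" in raw:
            sec = dict(raw["classifier"])
            if "ead_band" in sec:
                sec["ead_band"] = tuple(sec["ead_band"])
            kwargs["classifier"] = _build(ClassifierConfig, sec, "classifier")
        if "insults" in raw:
            specs = []
            for entry in raw["insults"]:
                if set(entry) - {"insult_type", "levels"}:
                    raise ConfigError(f"unknown keys in insult entry: {entry}")
                try:
                    specs.append(InsultSpec(entry["insult_type"],
                                            tuple(entry["levels"])))
                except (KeyError, ValueError) as e:
                    raise ConfigError(f"invalid insult entry: {e}") from e
            kwargs["insults"] = tuple(specs)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Optional[str]) -> "RunConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError("configuration file must hold a mapping")
        return cls.from_dict(raw or {})

    def to_dict(self) -> Dict:
        out = {k: getattr(self, k) for k in self._SIMPLE_KEYS}
        for k in ("drugs", "cell_lines", "ai_weights"):
            if out[k] is not None:
                out[k] = list(out[k])
        out["protocol"] = dataclasses.asdict(self.protocol)
        out["solver"] = dataclasses.asdict(self.solver)
        cls_dict = dataclasses.asdict(self.classifier)
        cls_dict["ead_band"] = list(cls_dict["ead_band"])
        out["classifier"] = cls_dict
        out["insults"] = [{"insult_type": s.insult_type,
                           "levels": list(s.levels)} for s in self.insults]
        return out

    def write_resolved(self, directory: Optional[str] = None) -> str:
        """Dump the fully resolved configuration next to the run outputs."""
        directory = directory or self.out_dir
        os.makedirs(directory, exist_ok=True)
        path = os.path.join(directory, "resolved_config.yaml")
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
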
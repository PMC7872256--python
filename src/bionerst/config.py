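"""Run configuration: YAML parsing with strict validation, seed expansion,
and run manifests.

A single YAML file mirrors the three config dataclasses::

    tagger:     {embed_dim: 200, hidden_units: 300, ...}
    selftrain:  {confidence_threshold: 0.9975, max_iterations: 30}
    scenario:   {labeled_sizes: [250, 500, 1000, 2000], seeds: [0], ...}
    seed:       0

Unknown keys are rejected so typos fail loudly.  One top-level seed expands
deterministically into per-stage seeds.  A RunManifest records everything
needed to re-run an experiment bit-identically on one machine; it is
written atomically (temp file + rename) at the end of a run.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__ as _version
from .tagger import TaggerConfig
from .workflow import ScenarioConfig, SelfTrainConfig


class ConfigError(ValueError):
    """Raised for schema violations in a run configuration."""


@dataclass(frozen=True)
class RunConfig:
    tagger: TaggerConfig = field(default_factory=TaggerConfig)
    selftrain: SelfTrainConfig = field(default_factory=SelfTrainConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the top-level seed."""
        offsets = {"simulate": 0, "pretrain": 1, "finetune": 2, "selftrain": 3,
                   "scenario": 4, "evaluate": 5}
        if stage not in offsets:
            raise ConfigError(f"unknown stage {stage!r}")
        return (self.seed * 7 + offsets[stage]) % (2**31 - 1)


def _build(cls, section: str, values: dict[str, Any]):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(values) - set(names)
    if unknown:
        raise ConfigError(
            f"{section}: unknown key {sorted(unknown)[0]!r} "
            f"(known: {sorted(names)})"
        )
    coerced = {}
    for key, value in values.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def parse_config(source: str | Path | dict | None) -> RunConfig:
    """Parse a YAML file (or an already-loaded mapping) into a validated
    RunConfig; missing sections get the package defaults (confidence
    threshold 0.9975, patience 5/10, batch 128, learning rate 1e-4, 80/20
    splits)."""
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, dict):
        raw = source
    else:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    known = {"tagger", "selftrain", "scenario", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key {sorted(unknown)[0]!r}")
    scenario_raw = dict(raw.get("scenario", {}))
    if "tagger" in scenario_raw:
        raise ConfigError("scenario: set the tagger in the top-level 'tagger' section")
    tagger = _build(TaggerConfig, "tagger", raw.get("tagger", {}))
    scenario = _build(
        ScenarioConfig, "scenario", {**scenario_raw, "tagger": tagger}
    )
    return RunConfig(
        tagger=tagger,
        selftrain=_build(SelfTrainConfig, "selftrain", raw.get("selftrain", {})),
        scenario=scenario,
        seed=int(raw.get("seed", 0)),
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class RunManifest:
    """Everything needed to reproduce one run on one machine."""

    command: str
    config: RunConfig
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    version: str = _version

    def write(self, path: str | Path) -> None:
        path = Path(path)
        payload = json.dumps(_jsonable(self), indent=2, sort_keys=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                fh.write(payload + "\n")
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def read(cls, path: str | Path) -> dict:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
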
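"""Pipeline configuration and run manifests.

One flat YAML file configures every stage; defaults reproduce the
reference analysis parameters (edit weights 1.1/1.1/1.9, lambda = 3,
graph filters 10 members / edge distance 8 / 60% of time points, active
fraction 0.95, top-50 subsets, ensemble of 10, noise grid 0-0.25).  The
run manifest records versions, configuration hash, input/output digests
and per-stage wall-clock so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from tcranet import __version__
from tcranet.distance import EditWeights
from tcranet.errors import ConfigurationError
from tcranet.ml import MLConfig
from tcranet.network import GraphFilters
from tcranet.simulate import SimConfig


@dataclass
class PipelineConfig:
    weights: EditWeights = field(default_factory=EditWeights)
    filters: GraphFilters = field(default_factory=GraphFilters)
    ml: MLConfig = field(default_factory=MLConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    strategy: str = "first_fit"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "weights": EditWeights,
            "filters": GraphFilters,
            "ml": MLConfig,
            "sim": SimConfig,
        }
        for key, typ in sections.items():
            sub = dict(raw.get(key, {}))
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown field(s) {sorted(unknown)} in config section {key!r}"
                )
            for name, value in sub.items():
                if isinstance(value, list):
                    sub[name] = tuple(value)
            kwargs[key] = typ(**sub)
        for key in ("strategy", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        extra = set(raw) - set(sections) - {"strategy", "seed"}
        if extra:
            raise ConfigurationError(f"unknown config section(s) {sorted(extra)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "weights": dataclasses.asdict(self.weights),
            "filters": dataclasses.asdict(self.filters),
            "ml": dataclasses.asdict(self.ml),
            "sim": dataclasses.asdict(self.sim),
            "strategy": self.strategy,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Inventory of one pipeline run, sufficient to re-run identically."""

    version: str = __version__
    config_hash: str = ""
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)    # path -> digest
    outputs: dict[str, str] = field(default_factory=dict)   # path -> digest
    stage_seconds: dict[str, float] = field(default_factory=dict)
    status: str = "ok"
    failed_stage: str | None = None

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    manifest.status = "failed"
                    manifest.failed_stage = name
                return False

        return _Timer()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
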
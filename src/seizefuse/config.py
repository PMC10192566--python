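"""YAML run configuration and provenance manifests.

One YAML file drives every CLI command.  Section names mirror the library
dataclasses (synthetic -> SyntheticSpec, preprocessing -> PreprocessConfig,
branch -> BranchConfig, training -> TrainConfig); unknown keys are
rejected with a report naming every offending field, and every artifact a
command writes is accompanied by a manifest carrying the config hash,
seed and package version so runs can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .networks import BranchConfig
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    branch: BranchConfig = field(default_factory=BranchConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    patient_id: str = "synthetic"

    def validate(self) -> None:
        self.synthetic.validate()
        self.branch.validate()
        self.training.validate()

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_section(cls, data: dict, section: str, errors: list[str]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    for key in sorted(unknown):
        errors.append(f"{section}.{key}: unknown field")
    kwargs = {k: v for k, v in data.items() if k in names}
    for f in dataclasses.fields(cls):
        if (f.name in kwargs and isinstance(f.default, tuple)
                and kwargs[f.name] is not None):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; raises with all problems listed."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in (overrides or {}).items():
        raw.setdefault(section, {}).update(values)

    errors: list[str] = []
    known = {"synthetic": SyntheticSpec, "preprocessing": PreprocessConfig,
             "branch": BranchConfig, "training": TrainConfig}
    for key in sorted(set(raw) - set(known) - {"patient_id"}):
        errors.append(f"{key}: unknown section")
    sections = {}
    for name, cls in known.items():
        try:
            sections[name] = _build_section(cls, raw.get(name, {}) or {},
                                            name, errors)
        except TypeError as exc:
            errors.append(f"{name}: {exc}")
    cfg = RunConfig(patient_id=raw.get("patient_id", "synthetic"), **sections)
    try:
        cfg.validate()
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def write_manifest(out_dir: str | Path, cfg: RunConfig, command: str,
                   extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "seed": cfg.training.seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest.update(extra or {})
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
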
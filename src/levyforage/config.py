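"""YAML configuration loading, validation, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evolution import EvolutionConfig
from .single_generation import SweepConfig

_KINDS = {"sweep": SweepConfig, "evolution": EvolutionConfig}


def load_config(path: str | Path, kind: str = "sweep"):
    """Load and validate a YAML config of the given kind.

    Unknown keys and out-of-range values are rejected with the offending
    field named.  Omitted keys take the package defaults (n = 1000, resource
    density 1e-4, s = 1, metric AOL).
    """
    cls = _KINDS.get(kind)
    if cls is None:
        raise ValueError(f"unknown config kind {kind!r}; expected one of {sorted(_KINDS)}")
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "u_range" in raw and raw["u_range"] is not None:
        raw["u_range"] = tuple(raw["u_range"])
    return cls(**raw).validate()


def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_hash(config) -> str:
    """Stable hash of the canonicalized config (changes iff the config does)."""
    payload = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Provenance record: config snapshot, seed, version, outputs, timings."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)
    wall_times: dict[str, float] = field(default_factory=dict)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def add_output(self, stage: str, path: str | Path, seconds: float | None = None):
        self.outputs[stage] = str(path)
        if seconds is not None:
            self.wall_times[stage] = seconds

    def write(self, path: str | Path) -> None:
        doc = {
            "config": self.config,
            "config_hash": self.hash,
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "wall_times": self.wall_times,
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def write_results(
    tables: dict[str, pd.DataFrame], manifest: RunManifest, out_dir: str | Path
) -> list[Path]:
    """Write each table as CSV with stable column order plus manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest.add_output(name, path)
        written.append(path)
    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    written.append(manifest_path)
    return written
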
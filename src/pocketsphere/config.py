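"""Pipeline configuration, seed derivation, and run manifests.

A single :class:`PipelineConfig` collects every stage's tunable with its
default; YAML round-trips losslessly and unknown keys are rejected.  A master
seed fans out to per-stage seeds through a counter-based hash so stages are
independently reproducible.  Every CLI run writes one :class:`RunManifest`
(config snapshot, seeds, input hashes, package version, stage timings).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "derive_seed", "RunManifest", "__version__"]

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Defaults are the pipeline's standard operating point."""

    # pocket stage
    ligand_radius: float = 6.0        # A, protein-atom selection around ligand
    probe_radius: float = 1.5         # A, solvent probe
    surface_density: float = 3.0      # vertices per A^2
    smooth_iterations: int = 4
    sphere_r_min: float = 1.0
    sphere_r_max: float = 4.0
    # property stage
    exposure_d_max: float = 3.0       # A, exposure-vector neighborhood
    pseudo_radius: float = 3.0        # A, vertex-to-center assignment
    hydrophobicity_radius: float = 4.5
    charge_cap: float = 30.0          # kT/e
    # map + network stage
    n_side: int = 16
    k_neighbors: int = 20
    poly_order: int = 3
    channels: tuple = (32, 64, 128, 256)
    embed_dim: int = 256
    margin: float = 1.0
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["channels"] = list(d["channels"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, Path) or (
                isinstance(source, str) and "\n" not in source
                and Path(source).is_file()):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "channels" in data:
            data["channels"] = tuple(data["channels"])
        return cls(**data)


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from a master seed and stage name."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Provenance record of one pipeline run."""

    def __init__(self, config: PipelineConfig, command: str):
        self.data = {
            "command": command,
            "package_version": __version__,
            "config": json.loads(json.dumps(asdict(config))),
            "seeds": {"master": config.seed},
            "inputs": {},
            "timings_s": {},
        }
        self._t0 = {}

    def add_input(self, path) -> None:
        self.data["inputs"][str(path)] = _sha256(path)

    def add_stage_seed(self, stage: str) -> int:
        seed = derive_seed(self.data["seeds"]["master"], stage)
        self.data["seeds"][stage] = seed
        return seed

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.data["timings_s"][stage] = round(
            time.perf_counter() - self._t0.pop(stage), 4)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=1, sort_keys=True))
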
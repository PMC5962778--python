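"""Configuration bundles, presets, YAML round-tripping and run manifests.

Two presets ship with the package:

* ``full`` — the full-scale study conditions: 15x15 area (60 cm), 238
  input units (210 visual + 18 proprioceptive + 10 corollary discharge),
  48 hidden units (24 + 24 partition), 8 outputs, 5.5*10^7 training steps,
  checkpoints every 10^6 steps, 10 seeds.
* ``scaled`` — a proportionally shrunken configuration for desk-scale
  experiments and the test suite: 9x9 area with 3x3-square blocks, a 9x8
  FOV (100 input units), 16 hidden units (8 + 8), 10^6 training steps,
  checkpoints every 10^5 steps, 3 seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decoding import DecoderConfig
from .encoding import InputLayout
from .experiment import RunConfig
from .network import NetworkConfig
from .rtrl import TrainerConfig
from .world import ConfigurationError, GridGeometry


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a run (except the seed)."""

    geometry: GridGeometry = field(default_factory=GridGeometry)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    trainer: TrainerConfig = field(default_factory=TrainerConfig)
    run: RunConfig = field(default_factory=RunConfig)
    proprio_value: float = 1.0
    cd_value: float = 1.0

    @property
    def layout(self) -> InputLayout:
        return InputLayout.from_geometry(
            self.geometry, self.proprio_value, self.cd_value
        )

    @property
    def n_inputs(self) -> int:
        return self.layout.total


def full_preset() -> SimulationConfig:
    """Full-scale study conditions (238-48-8 network, 5.5e7 steps)."""
    return SimulationConfig()


def scaled_preset() -> SimulationConfig:
    """Desk-scale preset: 9x9 area, 100-16-8 network, 1e6 steps, 3 seeds."""
    return SimulationConfig(
        geometry=GridGeometry(
            area_width=9, area_height=9, square_size=4.0, block_size=3
        ),
        network=NetworkConfig(n_hidden=16, n_agency=8),
        run=RunConfig(
            total_steps=1_000_000,
            checkpoint_period=100_000,
            train_obs_interval=50_000,
            train_obs_window=1_000,
            reposition_period=1_000,
            other_move_period=50,
            test_window=20_000,
            test_placements=20,
            n_seeds=3,
        ),
    )


PRESETS = {"full": full_preset, "scaled": scaled_preset}


def validate(config: SimulationConfig) -> SimulationConfig:
    """Check cross-field invariants; raises ``ConfigurationError`` naming
    the offending field."""
    g = config.geometry
    if g.area_width * g.square_size <= 0:
        raise ConfigurationError("geometry.square_size must be positive")
    layout = config.layout
    if layout.total != layout.n_visual + 18 + 10:
        raise ConfigurationError(
            "layout: total must equal visual + 18 proprio + 10 CD units"
        )
    run = config.run
    for name in ("checkpoint_period", "train_obs_interval"):
        period = getattr(run, name)
        if run.total_steps % period != 0:
            raise ConfigurationError(
                f"run.{name}={period} must divide total_steps={run.total_steps}"
            )
    if run.checkpoint_period % run.reposition_period != 0:
        raise ConfigurationError(
            "run.reposition_period must divide run.checkpoint_period"
        )
    if config.network.n_hidden < 2:
        raise ConfigurationError("network.n_hidden must be >= 2")
    return config


# -- serialization --------------------------------------------------------


def to_dict(config: SimulationConfig) -> dict:
    def section(obj):
        return dataclasses.asdict(obj)

    d = {
        "geometry": section(config.geometry),
        "network": section(config.network),
        "decoder": section(config.decoder),
        "trainer": section(config.trainer),
        "run": section(config.run),
        "proprio_value": config.proprio_value,
        "cd_value": config.cd_value,
    }
    # YAML-friendly tuples -> lists
    d["geometry"]["fov_cols"] = list(d["geometry"]["fov_cols"])
    d["geometry"]["fov_rows"] = list(d["geometry"]["fov_rows"])
    return d


def from_dict(d: dict) -> SimulationConfig:
    geom = dict(d.get("geometry", {}))
    for key in ("fov_cols", "fov_rows"):
        if key in geom and geom[key] is not None:
            geom[key] = tuple(geom[key])
    return SimulationConfig(
        geometry=GridGeometry(**geom),
        network=NetworkConfig(**d.get("network", {})),
        decoder=DecoderConfig(**d.get("decoder", {})),
        trainer=TrainerConfig(**d.get("trainer", {})),
        run=RunConfig(**d.get("run", {})),
        proprio_value=d.get("proprio_value", 1.0),
        cd_value=d.get("cd_value", 1.0),
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML/JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    try:
        config = from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    return validate(config)


def config_hash(config: SimulationConfig) -> str:
    """Stable SHA-256 of the canonical serialized config."""
    canonical = json.dumps(to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


# -- run manifests ---------------------------------------------------------


@dataclass
class RunManifest:
    """Inventory of one run directory: config hash, seeds, files, times."""

    config_hash: str
    seeds: list[int]
    files: list[str]
    created: float = field(default_factory=time.time)
    code_version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_manifest(
    directory: str | Path, config: SimulationConfig, seeds: list[int]
) -> Path:
    """Write ``manifest.json`` listing every file currently in ``directory``."""
    from . import __version__

    directory = Path(directory)
    files = sorted(
        str(p.relative_to(directory))
        for p in directory.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = RunManifest(
        config_hash=config_hash(config),
        seeds=list(seeds),
        files=files,
        code_version=__version__,
    )
    out = directory / "manifest.json"
    out.write_text(manifest.to_json())
    return out
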
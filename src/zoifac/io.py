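"""Configuration files, tidy CSV schemas and run manifests.

Configs are flat YAML/JSON mappings mirroring :class:`zoifac.growth.SimConfig`;
tables are tidy long-format CSV throughout (no binary formats are needed at
this scale).  Every CLI run writes a manifest tying outputs to the config
hash, master seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import RII_COLUMNS
from .geometry import Arena, SharingMode
from .growth import GrowthParams, SimConfig, default_growth_params

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "dict_to_config",
    "read_rii_csv",
    "write_rii_csv",
    "RunManifest",
]

_GROWTH_KEYS = ("a", "r", "M", "C0", "m0", "dt", "m_death")


def config_to_dict(config: SimConfig) -> dict:
    """Flatten a SimConfig into plain scalars for YAML/JSON."""
    d: dict = {
        "stress": config.stress,
        "n_plants": config.n_plants,
        "pattern": config.pattern,
        "n_steps": config.n_steps,
        "record_every": config.record_every,
        "seed": config.seed,
        "p": config.mode.p,
        "q": config.mode.q,
        "arena_width": config.arena.width,
        "arena_height": config.arena.height,
        "cell_area": config.arena.cell_area,
        "agg_cluster_size": config.agg_cluster_size,
        "agg_sigma": config.agg_sigma,
    }
    for key in _GROWTH_KEYS:
        d[key] = getattr(config.growth, key)
    return d


def dict_to_config(d: dict) -> SimConfig:
    """Inverse of :func:`config_to_dict`; missing keys take defaults."""
    d = dict(d)
    defaults = default_growth_params()
    growth = GrowthParams(
        **{key: float(d.pop(key, getattr(defaults, key))) for key in _GROWTH_KEYS}
    )
    mode = SharingMode(p=float(d.pop("p", 1.0)), q=float(d.pop("q", 1.0)))
    arena = Arena(
        width=int(d.pop("arena_width", 200)),
        height=int(d.pop("arena_height", 200)),
        cell_area=float(d.pop("cell_area", 1.0)),
    )
    known = {
        k: d.pop(k)
        for k in ("stress", "n_plants", "pattern", "n_steps", "record_every",
                  "seed", "agg_cluster_size", "agg_sigma")
        if k in d
    }
    if d:
        raise ValueError(f"unknown config keys: {sorted(d)}")
    return SimConfig(growth=growth, mode=mode, arena=arena, **known)


def load_config(path: str | Path) -> SimConfig:
    """Read a YAML or JSON simulation config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return dict_to_config(data)


def save_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def write_rii_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write an RII table with the documented column contract."""
    missing = [c for c in RII_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"RII table is missing columns {missing}")
    records.to_csv(path, index=False)


def read_rii_csv(path: str | Path) -> pd.DataFrame:
    """Read a replicate-level performance/RII table.

    This is also the reader contract for external (experimental) data: a
    tidy CSV with one row per replicate and columns stress, density,
    replicate, P_w, P_s and optionally RII.  If RII is absent it is computed
    from the performances.
    """
    df = pd.read_csv(path)
    required = ["stress", "density", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"RII table {path} is missing columns {missing}")
    if "RII" not in df.columns:
        if not {"P_w", "P_s"}.issubset(df.columns):
            raise ValueError("need either an RII column or both P_w and P_s")
        denom = df["P_w"] + df["P_s"]
        df["RII"] = (df["P_w"] - df["P_s"]) / denom.where(denom != 0)
    return df


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    master_seed: int
    config: dict
    version: str = __version__
    timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def mark(self, stage: str) -> None:
        self.timings[stage] = round(time.perf_counter() - self._t0, 3)
        self._t0 = time.perf_counter()

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        d = {
            "command": self.command,
            "master_seed": self.master_seed,
            "config_hash": self.config_hash,
            "config": self.config,
            "version": self.version,
            "timings": self.timings,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")
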
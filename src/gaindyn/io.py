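"""Configuration, manifests and result persistence.

Every persisted result file embeds a :class:`RunManifest` — a config
snapshot, package version, seeds and input-file digests — sufficient to
regenerate it from the input matrices alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .analysis import InfoResultGrid, SweepConfig
from .estimators import EmbeddingSpec
from .simulator import SimConfig

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "save_results",
    "load_results",
    "file_digest",
]

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_EMBED_KEYS = {f.name for f in dataclasses.fields(EmbeddingSpec)}
_SWEEP_KEYS = {
    "sigma_grid",
    "gamma_grid",
    "alpha",
    "measures",
    "master_seed",
    "jitter",
    "embedding",
    "simulation",
}


@dataclass(frozen=True)
class RunManifest:
    config: dict
    seeds: dict
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        return cls(**json.loads(s))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class ConfigError(ValueError):
    pass


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {section}: {sorted(unknown)}")


def load_config(path: str | Path) -> SweepConfig:
    """Load a sweep configuration from YAML, applying package defaults.

    An empty file yields the full default configuration (dt = 0.5 ms,
    duration = 50 000 ms, m = 1.5, k = 25, tau = 12, alpha = 0.05).  Unknown
    keys anywhere in the hierarchy are rejected with a list of offenders.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("root", raw, _SWEEP_KEYS)
    sim_raw = raw.pop("simulation", {}) or {}
    emb_raw = raw.pop("embedding", {}) or {}
    _check_keys("simulation", sim_raw, _SIM_KEYS)
    _check_keys("embedding", emb_raw, _EMBED_KEYS)
    try:
        sim = SimConfig(**sim_raw)
        emb = EmbeddingSpec(**emb_raw)
        for key in ("sigma_grid", "gamma_grid", "measures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return SweepConfig(sim=sim, embedding=emb, **raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def save_config(cfg: SweepConfig, path: str | Path) -> None:
    d = {
        "sigma_grid": [float(v) for v in cfg.sigma_grid],
        "gamma_grid": [float(v) for v in cfg.gamma_grid],
        "alpha": float(cfg.alpha),
        "measures": [str(m) for m in cfg.measures],
        "master_seed": int(cfg.master_seed),
        "jitter": float(cfg.jitter),
        "embedding": dataclasses.asdict(cfg.embedding),
        "simulation": dataclasses.asdict(cfg.sim),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


_ARRAY_FIELDS = [
    "sigma_grid",
    "gamma_grid",
    "edges",
    "order_param",
    "am_rate",
    "ipc",
    "te_rate",
    "cond_te_rate",
    "coll_te_rate",
    "te_pvalue",
    "all_pairs",
    "all_pairs_te",
    "all_pairs_sig",
    "missing",
    "fallback_delay_pairs",
]


def save_results(
    grid: InfoResultGrid,
    manifest: RunManifest,
    path: str | Path,
    *,
    force: bool = False,
) -> Path:
    """Persist a result grid to HDF5 with its manifest as a root attribute."""
    if manifest is None:
        raise ValueError("refusing to persist results without a manifest")
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = manifest.to_json()
        for name in _ARRAY_FIELDS:
            f.create_dataset(name, data=getattr(grid, name))
    return path


def load_results(path: str | Path) -> tuple[InfoResultGrid, RunManifest]:
    with h5py.File(path, "r") as f:
        manifest = RunManifest.from_json(f.attrs["manifest"])
        arrays = {name: f[name][...] for name in _ARRAY_FIELDS}
    arrays["missing"] = arrays["missing"].astype(bool)
    arrays["all_pairs_sig"] = arrays["all_pairs_sig"].astype(bool)
    return InfoResultGrid(**arrays), manifest
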
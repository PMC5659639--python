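"""Run configuration, deterministic seeding and stamped tabular output.

Configs are flat YAML key-value documents; unknown keys are rejected so a
typo cannot silently fall back to a default.  Every output file is stamped
with the config hash, the master seed and the package version, which makes
re-runs byte-identical and self-describing.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "write_results", "component_seed"]

FORMAT_VERSION = "1"


@dataclass
class RunConfig:
    model: str = "er"
    N: int = 1000
    K: float = 5.0
    gamma: float = math.inf        # infinity encodes the ER limit
    a: float = 0.05
    T: float = 0.0
    a_min: float = 0.005
    a_max: float = 1.0
    a_step: float = 0.005
    T_min: float = 0.01
    T_max: float = 2.0
    T_step: float = 0.05
    p: int = 1
    seed: int = 0
    seeds: int = 1
    init_overlap: float = 1.0
    max_sweeps: int = 200
    tolerance: float = 1e-11
    out_prefix: str = "results/run"
    format_version: str = FORMAT_VERSION

    def nu_equivalent(self) -> float:
        return 0.0 if math.isinf(self.gamma) else 1.0 / (self.gamma - 1.0)

    def normalized(self) -> dict:
        d = asdict(self)
        d["gamma"] = "inf" if math.isinf(self.gamma) else self.gamma
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.normalized(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a flat YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    known = {f.name: f.type for f in fields(RunConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "gamma" in raw and raw["gamma"] in ("inf", "Infinity", None):
        raw["gamma"] = math.inf
    cfg = RunConfig(**raw)
    # domain validation
    if not 0.0 <= cfg.nu_equivalent() < 1.0:
        raise ValueError(f"{path}: gamma={cfg.gamma} outside the admissible range (> 2)")
    if cfg.K <= 0 or cfg.N < 2:
        raise ValueError(f"{path}: need K > 0 and N >= 2")
    return cfg


def component_seed(master: int, component: str) -> int:
    """Derive a stable per-component seed from one master seed.

    Counter-based (hash of the component name), so adding a consumer never
    shifts the streams of existing ones.  Result fits in 31 bits.
    """
    h = hashlib.sha256(f"{master}:{component}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _stamp(cfg: RunConfig | None, seed=None) -> dict:
    from . import __version__
    st = {"format_version": FORMAT_VERSION, "package_version": __version__}
    if cfg is not None:
        st["config_hash"] = cfg.config_hash()
    if seed is not None:
        st["seed"] = seed
    return st


def write_results(obj, path, cfg: RunConfig | None = None, seed=None) -> None:
    """Write a DataFrame as stamped CSV or a mapping as pretty JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg, seed)
    import pandas as pd

    if isinstance(obj, pd.DataFrame):
        with open(path, "w") as fh:
            for k, v in stamp.items():
                fh.write(f"# {k}: {v}\n")
            obj.to_csv(fh, index=False, lineterminator="\n")
    else:
        payload = {**stamp, **_jsonable(obj)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj
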
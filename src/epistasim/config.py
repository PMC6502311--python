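"""Structured run configuration with strict validation.

Configurations are YAML mappings.  Every key has a default, unknown
keys are rejected with their full path, and a parsed configuration
serialises back to YAML losslessly, so a run manifest is sufficient to
reproduce a run bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from epistasim.fitness import DominanceParams
from epistasim.network import MEASURES, SyntheticNetworkSpec
from epistasim.simulate import SimulationConfig

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "network": {
        "path": None,           # prefix of a serialized network; overrides synthetic
        "measure": "multiplicative",
        "synthetic": {
            "n_loci": 1000,
            "s_weights": [0.05, 0.75, 0.20],
            "s_means": [-0.35, -0.03, 0.01],
            "s_sds": [0.10, 0.02, 0.01],
            "coupling": 0.2,
            "epsilon_noise_sd": 0.05,
            "pair_density": 0.35,
        },
    },
    "dominance": {
        "h": 0.5,
        "alpha1": 0.25,
        "alpha2": 0.5,
    },
    "simulation": {
        "effective_size": 1e6,
        "fixations_per_population": 50,
        "replicate_count": 1,
        "alternation": "strict",
        "rate_ratio": 1.0,
    },
    "analytic": {
        "eps_w": 0.02,
        "eps_b": 0.01,
        "v": 0.25,
        "alpha1": 0.25,
        "n_max": 50,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict):
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


@dataclass
class Config:
    """Validated configuration for every subcommand."""

    raw: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def dominance(self) -> DominanceParams:
        d = self.raw["dominance"]
        return DominanceParams(
            h_default=float(d["h"]),
            alpha1=float(d["alpha1"]),
            alpha2=float(d["alpha2"]),
        )

    def synthetic_spec(self) -> SyntheticNetworkSpec:
        s = self.raw["network"]["synthetic"]
        return SyntheticNetworkSpec(
            n_loci=int(s["n_loci"]),
            s_weights=tuple(s["s_weights"]),
            s_means=tuple(s["s_means"]),
            s_sds=tuple(s["s_sds"]),
            coupling=float(s["coupling"]),
            epsilon_noise_sd=float(s["epsilon_noise_sd"]),
            pair_density=float(s["pair_density"]),
            seed=self.seed,
        )

    def simulation(self) -> SimulationConfig:
        s = self.raw["simulation"]
        return SimulationConfig(
            effective_size=float(s["effective_size"]),
            fixations_per_population=int(s["fixations_per_population"]),
            dominance=self.dominance(),
            alternation=str(s["alternation"]),
            rate_ratio=float(s["rate_ratio"]),
            seed=self.seed,
            replicate_count=int(s["replicate_count"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def _validate(raw: dict[str, Any]) -> None:
    measure = raw["network"]["measure"]
    if measure not in MEASURES:
        raise ConfigError(f"network.measure: unknown measure {measure!r}")
    for key in ("alpha1", "alpha2"):
        v = raw["dominance"][key]
        if not 0 <= v <= 1:
            raise ConfigError(f"dominance.{key}: must lie in [0, 1], got {v}")
    if raw["simulation"]["effective_size"] < 2:
        raise ConfigError("simulation.effective_size: must be >= 2")
    if raw["simulation"]["fixations_per_population"] < 1:
        raise ConfigError("simulation.fixations_per_population: must be >= 1")
    v = raw["analytic"]["v"]
    if not 0 <= v <= 0.25:
        raise ConfigError(f"analytic.v: must lie in [0, 1/4], got {v}")


def parse_config(path: str | Path | None = None, text: str | None = None) -> Config:
    """Load and validate a YAML configuration, applying all defaults.

    An empty (or absent) file yields the full default set; unknown
    keys are fatal and reported with their key path.
    """
    if text is None:
        if path is None:
            user: dict = {}
        else:
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(path)
            user = yaml.safe_load(path.read_text()) or {}
    else:
        user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ConfigError("configuration must be a mapping")
    raw = _merge(_DEFAULTS, user)
    _validate(raw)
    return Config(raw=raw)


def write_manifest(
    out_dir: str | Path,
    config: Config,
    inputs: list[str | Path] = (),
    extra: dict | None = None,
) -> Path:
    """Write the run manifest (config snapshot, seed, version, digests)."""
    from epistasim import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {}
    for p in inputs:
        p = Path(p)
        digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config": config.raw,
        "seed": config.seed,
        "package_version": __version__,
        "input_digests": digests,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
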
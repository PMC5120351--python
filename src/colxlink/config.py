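"""Run configuration: every tunable the analysis stages expose.

Configuration files are YAML with one section per stage (``helix``,
``telo``, ``sites``, ``conservation``, ``synthetic``); unknown keys are
rejected so typos cannot silently fall back to defaults. The effective
configuration is echoed into every output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import helix_detect, sites, telopeptide, conservation
from .errors import ConfigError
from .sites import MotifModel


def _default_telo_weights() -> dict[int, dict[str, float]]:
    return {k: dict(v) for k, v in sites.DEFAULT_TELO_WEIGHTS.items()}


def _default_helix_weights() -> dict[int, dict[str, float]]:
    return {k: dict(v) for k, v in sites.DEFAULT_HELIX_WEIGHTS.items()}


@dataclass
class RunConfig:
    """All stage parameters with their package defaults."""

    # helix detection
    helix_min_triplets: int = helix_detect.DEFAULT_MIN_TRIPLETS
    helix_max_interruptions: int = helix_detect.DEFAULT_MAX_INTERRUPTIONS
    helix_minor_max_fraction: float = helix_detect.DEFAULT_MINOR_MAX_FRACTION
    helix_gpp_min_repeats: int = helix_detect.DEFAULT_GPP_MIN_REPEATS
    # telopeptide windows
    telo_c_max_len: int = telopeptide.DEFAULT_C_MAX_LEN
    # site scanning
    sites_score_min: float = sites.DEFAULT_SCORE_MIN
    sites_end_window: int = sites.DEFAULT_END_WINDOW
    sites_flank: int = sites.DEFAULT_FLANK
    sites_enforce_register: bool = True
    sites_telo_weights: dict = field(default_factory=_default_telo_weights)
    sites_telo_default_weight: float = sites.DEFAULT_TELO_DEFAULT
    sites_helix_weights: dict = field(default_factory=_default_helix_weights)
    sites_helix_default_weight: float = sites.DEFAULT_HELIX_DEFAULT
    # conservation
    conservation_flank_left: int = 2
    conservation_flank_right: int = 4
    conservation_pseudocount: float = 0.0
    conservation_f_k: float = conservation.DEFAULT_F_K
    # run plumbing
    seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = ("helix", "telo", "sites", "conservation")

    def telo_model(self) -> MotifModel:
        return MotifModel(
            weights={int(k): dict(v) for k, v in self.sites_telo_weights.items()},
            default=self.sites_telo_default_weight,
        )

    def helix_model(self) -> MotifModel:
        return MotifModel(
            weights={int(k): dict(v) for k, v in self.sites_helix_weights.items()},
            default=self.sites_helix_default_weight,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a nested mapping; unknown keys raise ConfigError."""
        known = {f.name for f in dataclasses.fields(cls)}
        flat: dict = {}
        for key, value in data.items():
            if key in cls._SECTIONS and isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}_{sub}"] = v
            else:
                flat[key] = value
        unknown = sorted(set(flat) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        """Nested mapping mirroring the YAML layout (for echoing)."""
        out: dict = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            parts = f.name.split("_", 1)
            if parts[0] in self._SECTIONS:
                out.setdefault(parts[0], {})[parts[1]] = value
            else:
                out[f.name] = value
        return out

    def echo(self, path: str | Path) -> None:
        """Write the effective configuration as YAML."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
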